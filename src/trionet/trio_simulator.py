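"""Synthetic family-trio generator: truth genotypes and pileup feature tensors.

The generator stands in for the upstream read-alignment stack.  Per candidate
site it draws an alt allele frequency, samples the two parents from
Hardy-Weinberg equilibrium at that frequency, transmits one uniformly chosen
allele from each parent to the child, and mutates each transmitted allele
with probability ``denovo_rate`` — so with rate m the expected fraction of
Mendelian-violating sites is 1 - (1-m)^2.  Reads are then rendered as pileup
tensors of 8 feature channels over a reference-centred window and a
read-depth axis, with a uniform per-base miscall probability standing in for
ONT base error and a perfectly phased haplotype-tag channel.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .genotype_space import Allele, Genotype21, allele_class_of_vcf_allele, encode_genotype
from .vcf_io import SiteCall, write_vcf

__all__ = [
    "SimConfig",
    "TrioTruthRecord",
    "TensorDataset",
    "PileupCallRecord",
    "simulate_truth",
    "render_tensors",
    "write_truth_vcfs",
    "simulate_pileup_calls",
    "coverage_mix_presets",
    "MEMBERS",
]

logger = logging.getLogger(__name__)

MEMBERS = ("child", "parent1", "parent2")
_BASES = "ACGT"

#: training-style coverage combinations: child depth high, parents downsampled
_COVERAGE_LEVELS = (10, 30, 60, 80)


def coverage_mix_presets() -> tuple[tuple[int, int], ...]:
    """(child, parents) mean-depth pairs with parents never above the child."""
    return tuple(
        (child, parent)
        for child in _COVERAGE_LEVELS
        for parent in _COVERAGE_LEVELS
        if parent <= child
    )


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated trio cohort.

    ``alt_af_spectrum`` draws per-site alt allele frequencies; the default is
    uniform on (0.05, 0.95), which exercises all Hardy-Weinberg genotype
    mixes at candidate sites.  ``base_error`` defaults to 0.05, an ONT-scale
    per-base miscall rate.
    """

    n_sites: int = 1000
    denovo_rate: float = 0.0
    coverage_child: float = 30.0
    coverage_p1: float = 15.0
    coverage_p2: float = 15.0
    base_error: float = 0.05
    indel_fraction: float = 0.1
    window: int = 33
    depth_rows: int = 55
    seed: int = 0
    contig: str = "chr1"
    alt_af_spectrum: Callable[[np.random.Generator, int], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if self.depth_rows < 1:
            raise ValueError("depth_rows must be >= 1")
        for name in ("denovo_rate", "base_error", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def sample_af(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.alt_af_spectrum is not None:
            return np.asarray(self.alt_af_spectrum(rng, n), dtype=np.float64)
        return rng.uniform(0.05, 0.95, size=n)


@dataclass(frozen=True)
class TrioTruthRecord:
    """Ground truth for one candidate site."""

    site_id: int
    contig: str
    position: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    genotypes: tuple[Genotype21, Genotype21, Genotype21]  # (child, parent1, parent2)
    gt_indices: tuple[tuple[int, int], ...]  # VCF allele-index pairs, family order
    alt_af: float
    is_denovo: bool
    child_hap_origin: tuple[int, int] = (0, 1)  # parental origin of the child's alleles


@dataclass
class TensorDataset:
    """Rendered candidate tensors with aligned truth labels.

    ``tensors`` is the trio-stacked block (N, 8, window, 3 * depth_rows):
    each of the 8 channels carries the three samples' read rows concatenated
    in family order child, parent1, parent2.  ``labels`` holds the genotype
    class index per member, shape (N, 3).
    """

    tensors: np.ndarray
    labels: np.ndarray
    site_ids: np.ndarray
    window: int
    depth_rows: int
    family_order: tuple[str, ...] = MEMBERS
    channel_roles: tuple[str, ...] = (
        "reference_base",
        "read_base",
        "base_quality",
        "mapping_quality",
        "strand",
        "insertion_flag",
        "deletion_flag",
        "haplotype_tag",
    )

    def __len__(self) -> int:
        return self.tensors.shape[0]

    def sample_block(self, member: str) -> np.ndarray:
        """Single-sample view (N, 8, window, depth_rows) of the stacked tensor."""
        s = self.family_order.index(member)
        d = self.depth_rows
        return self.tensors[:, :, :, s * d : (s + 1) * d]

    def subset(self, idx: np.ndarray) -> "TensorDataset":
        return TensorDataset(
            self.tensors[idx], self.labels[idx], self.site_ids[idx], self.window, self.depth_rows
        )

    def save(self, path: str | Path) -> None:
        """Binary tensor container plus a JSON sidecar describing the layout."""
        path = Path(path)
        np.savez_compressed(
            path.with_suffix(".npz"),
            tensors=self.tensors.astype(np.float32),
            labels=self.labels,
            site_ids=self.site_ids,
        )
        sidecar = {
            "shape": list(self.tensors.shape),
            "window": self.window,
            "depth_rows": self.depth_rows,
            "family_order": list(self.family_order),
            "channel_roles": list(self.channel_roles),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TensorDataset":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as data:
            return cls(
                tensors=data["tensors"],
                labels=data["labels"],
                site_ids=data["site_ids"],
                window=sidecar["window"],
                depth_rows=sidecar["depth_rows"],
                family_order=tuple(sidecar["family_order"]),
                channel_roles=tuple(sidecar["channel_roles"]),
            )


@dataclass(frozen=True)
class PileupCallRecord:
    """Abstracted upstream per-sample call: the pipeline's candidate input."""

    contig: str
    position: int
    sample_id: str
    call_type: str  # "variant" | "reference"
    alt_fraction: float
    quality: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise ValueError("alt_fraction must lie in [0, 1]")


def _allele_value(classes: np.ndarray) -> np.ndarray:
    """Numeric encoding of allele classes, centred on [-1, 1].

    A zero-mean spread (A=-1 ... Del=+1) conditions the convolutional stack
    far better than a one-sided encoding.
    """
    return (classes.astype(np.float64) - 2.5) / 2.5


def simulate_truth(config: SimConfig) -> list[TrioTruthRecord]:
    """Draw per-site trio truth genotypes under Mendelian inheritance.

    Parents follow Hardy-Weinberg at the site's sampled alt allele frequency;
    the child inherits one uniformly chosen allele per parent, each replaced
    by the site's other allele with probability ``denovo_rate``.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    positions = 10_000 + np.cumsum(rng.integers(5, 50, size=n))
    ref_bases = rng.integers(0, 4, size=n)
    is_indel = rng.random(n) < config.indel_fraction
    is_ins = is_indel & (rng.random(n) < 0.5)
    is_del = is_indel & ~is_ins
    alt_snp = (ref_bases + rng.integers(1, 4, size=n)) % 4
    af = config.sample_af(rng, n)

    parent_alleles = (rng.random((n, 2, 2)) < af[:, None, None]).astype(np.int8)  # (site, parent, hap)
    pick = rng.integers(0, 2, size=(n, 2))  # child's chosen haplotype per parent
    transmitted = parent_alleles[np.arange(n)[:, None], [0, 1], pick]
    mutate = rng.random((n, 2)) < config.denovo_rate
    child_alleles = np.where(mutate, 1 - transmitted, transmitted)
    is_denovo = mutate.any(axis=1)

    ref_class = ref_bases.copy()
    alt_class = np.where(is_ins, Allele.Ins, np.where(is_del, Allele.Del, alt_snp))

    records: list[TrioTruthRecord] = []
    for i in range(n):
        r = _BASES[ref_bases[i]]
        if is_ins[i]:
            ref, alt = r, r + "A"
        elif is_del[i]:
            ref, alt = r + "A", r
        else:
            ref, alt = r, _BASES[alt_snp[i]]
        pairs = (
            tuple(int(a) for a in sorted(child_alleles[i])),
            tuple(int(a) for a in sorted(parent_alleles[i, 0])),
            tuple(int(a) for a in sorted(parent_alleles[i, 1])),
        )
        classes = (int(ref_class[i]), int(alt_class[i]))
        genotypes = tuple(
            encode_genotype(Allele(classes[a]), Allele(classes[b])) for a, b in pairs
        )
        records.append(
            TrioTruthRecord(
                site_id=i,
                contig=config.contig,
                position=int(positions[i]),
                ref=ref,
                alts=(alt,),
                genotypes=genotypes,  # type: ignore[arg-type]
                gt_indices=pairs,
                alt_af=float(af[i]),
                is_denovo=bool(is_denovo[i]),
                child_hap_origin=(0, 1),
            )
        )
    return records


def _truth_arrays(truth: Sequence[TrioTruthRecord]) -> dict[str, np.ndarray]:
    n = len(truth)
    ref_class = np.empty(n, dtype=np.int64)
    alt_class = np.empty(n, dtype=np.int64)
    member_alleles = np.empty((n, 3, 2), dtype=np.int64)  # 0 = ref, 1 = alt
    for i, rec in enumerate(truth):
        ref_class[i] = int(allele_class_of_vcf_allele(rec.ref, rec.ref))
        alt_class[i] = int(allele_class_of_vcf_allele(rec.alts[0], rec.ref))
        member_alleles[i] = np.asarray(rec.gt_indices)
    return {"ref_class": ref_class, "alt_class": alt_class, "member_alleles": member_alleles}


def render_tensors(truth: Sequence[TrioTruthRecord], config: SimConfig) -> TensorDataset:
    """Render per-site pileup tensors for all three members, trio-stacked.

    Each sample draws Poisson(coverage) reads (capped at ``depth_rows`` by
    uniform subsampling); every read carries one of the sample's two alleles,
    miscalled per base with probability ``base_error``.  Unused rows stay
    zero-padded.  The haplotype-tag channel encodes which of the sample's two
    haplotypes a read came from (phasing is treated as perfect).
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7E45]))
    n = len(truth)
    w, d = config.window, config.depth_rows
    arrays = _truth_arrays(truth)
    site_classes = np.stack([arrays["ref_class"], arrays["alt_class"]], axis=1)  # (n, 2)

    # flanking reference context, shared by all reads of a site
    flank = rng.integers(0, 4, size=(n, w))
    flank[:, w // 2] = arrays["ref_class"]

    coverages = (config.coverage_child, config.coverage_p1, config.coverage_p2)
    blocks = []
    labels = np.empty((n, 3), dtype=np.int16)
    for i, rec in enumerate(truth):
        for s in range(3):
            labels[i, s] = rec.genotypes[s].index

    overflow = 0
    for s, cov in enumerate(coverages):
        draws = rng.poisson(cov, size=n)
        overflow += int((draws > d).sum())  # reads are iid, so truncation == uniform subsample
        n_reads = np.minimum(draws, d)
        active = np.arange(d)[None, :] < n_reads[:, None]  # (n, d)

        hap = rng.integers(0, 2, size=(n, d))  # which of the sample's two alleles
        read_allele = arrays["member_alleles"][:, s, :][np.arange(n)[:, None], hap]  # 0/1
        read_class_center = site_classes[np.arange(n)[:, None], read_allele]  # (n, d)

        base = np.broadcast_to(flank[:, :, None], (n, w, d)).copy()
        base[:, w // 2, :] = read_class_center
        err = rng.random((n, w, d)) < config.base_error
        base = np.where(err, (base + rng.integers(1, 6, size=(n, w, d))) % 6, base)

        block = np.zeros((n, 8, w, d), dtype=np.float32)
        block[:, 0] = _allele_value(np.broadcast_to(arrays["ref_class"][:, None, None], (n, w, d)))
        block[:, 1] = _allele_value(base)
        block[:, 2] = rng.uniform(0.5, 1.0, size=(n, w, d))
        block[:, 3] = rng.uniform(0.7, 1.0, size=(n, w, d))
        block[:, 4] = rng.choice([-1.0, 1.0], size=(n, w, d))
        block[:, 5] = (base == int(Allele.Ins)).astype(np.float64)
        block[:, 6] = (base == int(Allele.Del)).astype(np.float64)
        block[:, 7] = np.broadcast_to(((hap + 1) / 2.0)[:, None, :], (n, w, d))
        block *= active[:, None, None, :]
        blocks.append(block)

    if overflow:
        logger.info("subsampled %d read sets exceeding depth_rows", overflow)
    tensors = np.concatenate(blocks, axis=3)  # depth axis triples, family order
    return TensorDataset(
        tensors=tensors,
        labels=labels,
        site_ids=np.array([rec.site_id for rec in truth]),
        window=w,
        depth_rows=d,
    )


def write_truth_vcfs(
    truth: Sequence[TrioTruthRecord], out_prefix: str | Path
) -> dict[str, Path]:
    """One position-sorted VCF per family member, GT matching the truth."""
    if not truth:
        raise ValueError("truth must be non-empty")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for s, member in enumerate(MEMBERS):
        calls = [
            SiteCall(
                contig=rec.contig,
                pos=rec.position,
                ref=rec.ref,
                alts=rec.alts,
                gt=tuple(rec.gt_indices[s]),
                qual=60.0,
            )
            for rec in truth
        ]
        paths[member] = write_vcf(out_prefix.with_name(out_prefix.name + f".{member}.vcf"), calls, sample=member)
    return paths


def simulate_pileup_calls(
    truth: Sequence[TrioTruthRecord], config: SimConfig
) -> dict[str, list[PileupCallRecord]]:
    """Fabricate upstream per-sample pileup calls for candidate selection.

    The observed alt fraction is the member's true allele-dosage fraction
    plus binomial sampling noise at the member's coverage; variant calls get
    higher confidence than reference calls, with noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x51EB]))
    coverages = (config.coverage_child, config.coverage_p1, config.coverage_p2)
    out: dict[str, list[PileupCallRecord]] = {m: [] for m in MEMBERS}
    for s, (member, cov) in enumerate(zip(MEMBERS, coverages)):
        for rec in truth:
            dosage = sum(rec.gt_indices[s]) / 2.0
            depth = max(int(rng.poisson(cov)), 1)
            frac = rng.binomial(depth, np.clip(dosage + config.base_error * (1 - 2 * dosage), 0, 1)) / depth
            is_var = dosage > 0
            quality = float(np.clip(rng.normal(25 if is_var else 15, 6), 1, 60))
            out[member].append(
                PileupCallRecord(
                    contig=rec.contig,
                    position=rec.position,
                    sample_id=member,
                    call_type="variant" if is_var else "reference",
                    alt_fraction=float(frac),
                    quality=quality,
                )
            )
    return out
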