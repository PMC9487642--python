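"""Candidate selection, training-data hygiene, two-stage training and calling.

Candidate sites are taken per sample from upstream pileup calls — every
variant call with alt allele fraction above 0.08 plus the lowest-quality 20%
stratum of reference calls — and united across the family, so each member is
genotyped at every site any member flagged.  Training labels are purged of
Mendelian-violating sites before fitting.  Training itself is two-step:
stage 1 optimizes the focal terms alone (alpha = 0) at the default learning
rate, stage 2 fine-tunes from the stage-1 weights with MCVLoss enabled at a
lower learning rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotype_space import Allele, Genotype21, allele_class_of_vcf_allele, mismatch_count
from .losses import LossConfig, focal_grad_logits, focal_loss, mcv_grad_probs, mcv_loss, softmax
from .network import NetworkModel
from .nn import Adam
from .trio_simulator import MEMBERS, PileupCallRecord, TensorDataset, TrioTruthRecord
from .vcf_io import SiteCall, write_vcf

__all__ = [
    "TrainConfig",
    "TrioCallSet",
    "TrainingDiverged",
    "select_candidates",
    "union_trio_candidates",
    "mcv_filter_training_sites",
    "mix_coverage_datasets",
    "train",
    "train_stage",
    "call_variants",
]

logger = logging.getLogger(__name__)

SiteKey = tuple[str, int]


class TrainingDiverged(RuntimeError):
    """Loss became non-finite; carries the last finite weight state."""

    def __init__(self, message: str, checkpoint: NetworkModel):
        super().__init__(message)
        self.checkpoint = checkpoint


@dataclass(frozen=True)
class TrainConfig:
    """Two-stage optimization settings.

    Stage 1 trains from scratch without the Mendelian penalty at
    ``stage1_lr``; stage 2 fine-tunes with the configured alpha at the lower
    ``stage2_lr``.
    """

    stage1_lr: float = 1e-3
    stage2_lr: float = 1e-5
    stage1_epochs: int = 2
    stage2_epochs: int = 1
    batch_size: int = 128
    seed: int = 0
    retention_fraction: float = 0.3
    loss: LossConfig = field(default_factory=LossConfig)

    def __post_init__(self) -> None:
        if not self.stage2_lr < self.stage1_lr:
            raise ValueError("stage2_lr must be lower than stage1_lr")


# --- candidate selection ------------------------------------------------------


def select_candidates(
    calls: Sequence[PileupCallRecord],
    af_threshold: float = 0.08,
    ref_keep_fraction: float = 0.20,
    rng_seed: int = 0,
) -> set[SiteKey]:
    """Candidate sites for one sample from its upstream pileup calls.

    Keeps every variant call with alt fraction above ``af_threshold`` plus
    the lowest-quality ``ref_keep_fraction`` stratum of reference calls
    (quality ties broken by a seeded jitter, so the draw is deterministic).
    """
    variants = {
        (c.contig, c.position)
        for c in calls
        if c.call_type == "variant" and c.alt_fraction > af_threshold
    }
    refs = [c for c in calls if c.call_type == "reference"]
    n_keep = int(round(ref_keep_fraction * len(refs)))
    rng = np.random.default_rng(rng_seed)
    jitter = rng.random(len(refs)) * 1e-9
    order = np.argsort([c.quality + j for c, j in zip(refs, jitter)], kind="stable")
    low_quality = {(refs[i].contig, refs[i].position) for i in order[:n_keep]}
    return variants | low_quality


def union_trio_candidates(
    child_sites: set[SiteKey], p1_sites: set[SiteKey], p2_sites: set[SiteKey]
) -> list[SiteKey]:
    """Sorted union of the three members' candidate sites."""
    return sorted(child_sites | p1_sites | p2_sites)


def mcv_filter_training_sites(
    truth: Sequence[TrioTruthRecord],
) -> tuple[list[TrioTruthRecord], dict]:
    """Drop truth sites whose trio genotype violates Mendelian inheritance."""
    kept = [
        rec
        for rec in truth
        if mismatch_count(rec.genotypes[0], rec.genotypes[1], rec.genotypes[2]) == 0
    ]
    n_removed = len(truth) - len(kept)
    report = {
        "n_input": len(truth),
        "n_removed": n_removed,
        "removed_fraction": n_removed / len(truth) if truth else 0.0,
    }
    return kept, report


def mix_coverage_datasets(
    datasets: dict[tuple[int, int], TensorDataset],
    retention_fraction: float = 0.3,
    seed: int = 0,
) -> TensorDataset:
    """Assemble a multi-coverage training set from per-combination datasets.

    Each (child, parent) coverage combination contributes a random
    ``retention_fraction`` subset of its sites, balancing training-set size
    against coverage diversity.  Deterministic under the seed.
    """
    if not 0.0 < retention_fraction <= 1.0:
        raise ValueError("retention_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    parts = []
    for key in sorted(datasets):
        ds = datasets[key]
        n_keep = max(int(round(retention_fraction * len(ds))), 1)
        idx = np.sort(rng.permutation(len(ds))[:n_keep])
        parts.append(ds.subset(idx))
    first = parts[0]
    return TensorDataset(
        tensors=np.concatenate([p.tensors for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        site_ids=np.concatenate([p.site_ids for p in parts]),
        window=first.window,
        depth_rows=first.depth_rows,
    )


# --- training -----------------------------------------------------------------


def _softmax_chain(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Map d(loss)/d(probs) to d(loss)/d(logits) through the softmax."""
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)


def train_stage(
    model: NetworkModel,
    tensors: np.ndarray,
    labels: dict[str, np.ndarray],
    lr: float,
    epochs: int,
    config: TrainConfig,
    alpha: float | None = None,
) -> list[dict]:
    """Optimize the model in place for ``epochs`` passes; returns the history.

    ``labels`` maps each of the model's output samples to genotype class
    indices.  The Mendelian term applies only when all three trio heads are
    present and ``alpha`` > 0.
    """
    loss_cfg = config.loss if alpha is None else LossConfig(
        alpha=alpha,
        epsilon=config.loss.epsilon,
        mu=config.loss.mu,
        focal_gamma=config.loss.focal_gamma,
        l2_weight=config.loss.l2_weight,
    )
    for name in model.out_samples:
        if name not in labels:
            raise ValueError(f"labels missing for output sample {name!r}")
        if len(labels[name]) != tensors.shape[0]:
            raise ValueError("labels misaligned with tensor batch")
    use_mcv = loss_cfg.alpha > 0 and set(model.out_samples) == set(MEMBERS)
    beta = loss_cfg.beta_table() if use_mcv else None
    opt = Adam(model.params, lr=lr, l2_weight=loss_cfg.l2_weight)
    rng = np.random.default_rng(config.seed)
    n = tensors.shape[0]
    history: list[dict] = []
    for epoch in range(epochs):
        order = rng.permutation(n)
        sums: dict[str, float] = {f"focal_{s}": 0.0 for s in model.out_samples}
        sums["mcv"] = 0.0
        n_batches = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            xb = tensors[idx]
            opt.zero_grad()
            logits = model.forward_logits(xb)
            probs = {s: softmax(logits[s]["genotype21"]) for s in model.out_samples}
            dlogits: dict[str, dict[str, np.ndarray]] = {}
            batch_loss = 0.0
            for s in model.out_samples:
                yb = labels[s][idx]
                term = focal_loss(yb, probs[s], loss_cfg.focal_gamma, loss_cfg.epsilon)
                sums[f"focal_{s}"] += term
                batch_loss += term
                dlogits[s] = {
                    "genotype21": focal_grad_logits(yb, probs[s], loss_cfg.focal_gamma, loss_cfg.epsilon)
                }
            if use_mcv:
                term = mcv_loss(probs["child"], probs["parent1"], probs["parent2"], loss_cfg, beta)
                sums["mcv"] += term
                batch_loss += term
                grads = mcv_grad_probs(
                    probs["child"], probs["parent1"], probs["parent2"], loss_cfg, beta
                )
                for s, g in zip(MEMBERS, grads):
                    dlogits[s]["genotype21"] += _softmax_chain(probs[s], g)
            if not math.isfinite(batch_loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}", checkpoint=model.copy()
                )
            model.backward(dlogits)
            opt.step()
            n_batches += 1
        record = {k: v / max(n_batches, 1) for k, v in sums.items()}
        record.update(epoch=epoch, lr=lr, alpha=loss_cfg.alpha, l2=model.l2_term())
        record["total"] = sum(v for k, v in record.items() if k.startswith(("focal_", "mcv")))
        history.append(record)
        logger.info("epoch %d: %s", epoch, record)
    return history


def train(
    model: NetworkModel,
    data: TensorDataset | np.ndarray,
    labels: dict[str, np.ndarray] | None = None,
    config: TrainConfig | None = None,
) -> tuple[NetworkModel, dict[str, list[dict]]]:
    """Two-step procedure: focal-only initial training, then MCVLoss fine-tuning.

    ``data`` may be a TensorDataset (trio-stacked tensors and labels) or a
    raw tensor array accompanied by an explicit ``labels`` mapping.
    """
    config = config or TrainConfig()
    if isinstance(data, TensorDataset):
        tensors = data.tensors
        labels = {m: data.labels[:, i] for i, m in enumerate(MEMBERS)}
    else:
        tensors = np.asarray(data)
        if labels is None:
            raise ValueError("labels required when data is a raw tensor array")
    history = {
        "stage1": train_stage(
            model, tensors, labels, config.stage1_lr, config.stage1_epochs, config, alpha=0.0
        ),
        "stage2": train_stage(
            model, tensors, labels, config.stage2_lr, config.stage2_epochs, config, alpha=None
        ),
    }
    return model, history


# --- calling ------------------------------------------------------------------


def _phred_qual(p_max: float, cap: float = 60.0) -> float:
    return float(min(cap, -10.0 * math.log10(max(1.0 - p_max, 10.0 ** (-cap / 10.0)))))


def _genotype_to_gt(
    genotype: Genotype21, ref: str, alts: tuple[str, ...]
) -> tuple[tuple[int, int], tuple[str, ...]]:
    """Express a 21-class genotype as VCF GT indices against a site's alleles.

    Alleles outside the site's REF/ALT classes get a new ALT appended: bases
    as substitutions, Ins as REF+'A', Del as the anchored deletion when REF
    is long enough, else the symbolic <DEL>.
    """
    ref_class = allele_class_of_vcf_allele(ref, ref)
    site_alts = list(alts)

    def index_of(cls: Allele) -> int:
        if cls == ref_class:
            return 0
        for i, alt in enumerate(site_alts):
            if allele_class_of_vcf_allele(alt, ref) == cls:
                return i + 1
        if cls == Allele.Ins:
            new = ref + "A"
        elif cls == Allele.Del:
            new = ref[0] if len(ref) > 1 else "<DEL>"
        else:
            new = cls.name + ref[1:]
        site_alts.append(new)
        return len(site_alts)

    pair = tuple(sorted(index_of(c) for c in genotype.alleles))
    return pair, tuple(site_alts)  # type: ignore[return-value]


@dataclass
class TrioCallSet:
    """Per-site trio genotype calls with qualities; serializable to three VCFs."""

    calls: dict[str, list[SiteCall]]

    def write_vcfs(self, out_prefix: str | Path, variant_only: bool = False) -> dict[str, Path]:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {}
        for member, calls in self.calls.items():
            emit = [c for c in calls if not (variant_only and c.is_ref_call)]
            paths[member] = write_vcf(
                out_prefix.with_name(out_prefix.name + f".{member}.vcf"), emit, sample=member
            )
        return paths


def call_variants(
    model: NetworkModel,
    dataset: TensorDataset,
    sites: Sequence[TrioTruthRecord],
    qual_from: str = "max-prob",
    missing_site_ids: set[int] | None = None,
) -> TrioCallSet:
    """Argmax genotype per union site per member, with Phred-scaled quality.

    ``sites`` supplies the site context (contig, position, REF/ALT) for every
    tensor row, in dataset order.  Sites listed in ``missing_site_ids`` are
    emitted with missing genotypes.
    """
    if qual_from != "max-prob":
        raise ValueError("only max-prob quality derivation is supported")
    site_by_id = {rec.site_id: rec for rec in sites}
    from .network import predict  # local import avoids a cycle at module load

    pred = predict(model, dataset.tensors, site_ids=dataset.site_ids)
    dists = {"child": pred.p_child, "parent1": pred.p_parent1, "parent2": pred.p_parent2}
    missing_site_ids = missing_site_ids or set()
    calls: dict[str, list[SiteCall]] = {m: [] for m in MEMBERS}
    for row, site_id in enumerate(dataset.site_ids):
        rec = site_by_id[int(site_id)]
        for member in MEMBERS:
            dist = dists[member]
            if int(site_id) in missing_site_ids or dist is None:
                calls[member].append(
                    SiteCall(rec.contig, rec.position, rec.ref, rec.alts, (None, None), qual=None)
                )
                continue
            p = dist[row]
            g = Genotype21(int(p.argmax()))
            gt, alts = _genotype_to_gt(g, rec.ref, rec.alts)
            calls[member].append(
                SiteCall(rec.contig, rec.position, rec.ref, alts, gt, qual=_phred_qual(float(p.max())))
            )
    return TrioCallSet(calls=calls)
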