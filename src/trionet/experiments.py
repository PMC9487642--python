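"""Desk-scale trio-calling studies: training arms, ablations and alpha sweeps.

This module packages the end-to-end synthetic experiment used to exercise the
whole stack: simulate a family-trio cohort, train a Trio-to-Trio Model-A
network in the two-step procedure, fine-tune control arms with different
Mendelian-penalty weights, train a One-to-One ablation on the same data, and
measure held-out genotype F1 and Mendelian-violation counts.

Problem sizes are deliberately desk-scale: a 50k-site cohort with tensors of
window 5 x 12 read rows per sample, training on 12k Mendelian-clean sites
and holding out 6k sites, trains in minutes on one CPU while reproducing the
qualitative behaviour of full-scale trio callers (violations fall when the
Mendelian penalty is enabled; trio input beats single-sample input).
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genotype_space import MISMATCH_TABLE
from .losses import LossConfig
from .network import ModelConfig, NetworkModel, build_model, predict
from .pipeline import TrainConfig, call_variants, mcv_filter_training_sites, train_stage
from .trio_simulator import (
    MEMBERS,
    SimConfig,
    TensorDataset,
    render_tensors,
    simulate_truth,
    write_truth_vcfs,
)
from .trio_eval import score_calls

__all__ = ["StudyConfig", "StudyData", "TrioStudy"]


@dataclass(frozen=True)
class StudyConfig:
    """Conditions of the scaled synthetic study."""

    n_sites: int = 50_000
    train_sites: int = 14_000
    heldout_sites: int = 6_000
    coverage_child: float = 30.0
    coverage_parents: float = 15.0
    base_error: float = 0.05
    denovo_rate: float = 0.001
    window: int = 5
    depth_rows: int = 12
    model: ModelConfig = field(default_factory=lambda: ModelConfig(shape="A"))
    stage1_epochs: int = 8
    stage2_epochs: int = 2
    batch_size: int = 32
    stage1_lr: float = 1e-3
    stage2_lr: float = 1e-5

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(
            n_sites=self.n_sites,
            denovo_rate=self.denovo_rate,
            coverage_child=self.coverage_child,
            coverage_p1=self.coverage_parents,
            coverage_p2=self.coverage_parents,
            base_error=self.base_error,
            window=self.window,
            depth_rows=self.depth_rows,
            seed=seed,
        )

    def train_config(self, seed: int, alpha: float = 1.0) -> TrainConfig:
        return TrainConfig(
            stage1_lr=self.stage1_lr,
            stage2_lr=self.stage2_lr,
            stage1_epochs=self.stage1_epochs,
            stage2_epochs=self.stage2_epochs,
            batch_size=self.batch_size,
            seed=seed,
            loss=LossConfig(alpha=alpha),
        )


@dataclass
class StudyData:
    """A simulated cohort split into Mendelian-clean training data and held-out sites."""

    truth: list
    train_ds: TensorDataset
    held_ds: TensorDataset
    held_truth: list
    mcv_report: dict


class TrioStudy:
    """Runs and caches the arms of the scaled trio-calling experiment."""

    def __init__(self, config: StudyConfig | None = None, data_seed: int = 2026):
        self.config = config or StudyConfig()
        self.data_seed = data_seed
        self._data: StudyData | None = None

    # -- data -----------------------------------------------------------------

    @property
    def data(self) -> StudyData:
        if self._data is None:
            self._data = self._prepare()
        return self._data

    def _prepare(self) -> StudyData:
        cfg = self.config
        truth = simulate_truth(cfg.sim_config(self.data_seed))
        dataset = render_tensors(truth, cfg.sim_config(self.data_seed))
        kept, report = mcv_filter_training_sites(truth)
        kept_ids = np.isin(dataset.site_ids, [r.site_id for r in kept])
        train_pool = np.where(kept_ids)[0]
        train_idx = train_pool[: cfg.train_sites]
        held_idx = np.arange(len(truth) - cfg.heldout_sites, len(truth))
        return StudyData(
            truth=truth,
            train_ds=dataset.subset(train_idx),
            held_ds=dataset.subset(held_idx),
            held_truth=truth[len(truth) - cfg.heldout_sites :],
            mcv_report=report,
        )

    # -- training arms --------------------------------------------------------

    def _labels(self, ds: TensorDataset) -> dict[str, np.ndarray]:
        return {m: ds.labels[:, i] for i, m in enumerate(MEMBERS)}

    def train_initial(self, seed: int) -> NetworkModel:
        """Stage 1: focal-only training of the Trio-to-Trio model."""
        cfg = self.config
        model = build_model(cfg.model, self.data.train_ds.tensors.shape[1:], seed=seed)
        tc = cfg.train_config(seed)
        train_stage(
            model, self.data.train_ds.tensors, self._labels(self.data.train_ds),
            tc.stage1_lr, tc.stage1_epochs, tc, alpha=0.0,
        )
        return model

    def finetune(self, model: NetworkModel, seed: int, alpha: float) -> NetworkModel:
        """Stage 2 from given weights at the lower learning rate."""
        cfg = self.config
        out = model.copy()
        tc = cfg.train_config(seed, alpha=alpha)
        train_stage(
            out, self.data.train_ds.tensors, self._labels(self.data.train_ds),
            tc.stage2_lr, tc.stage2_epochs, tc, alpha=alpha,
        )
        return out

    def train_one_to_one(self, seed: int) -> NetworkModel:
        """Ablation: a single-sample model on the pooled per-member blocks.

        The pooled pool is subsampled to the trio arm's site count so both
        architectures see the same number of training examples.
        """
        cfg = self.config
        ds = self.data.train_ds
        pooled = np.concatenate([ds.sample_block(m) for m in MEMBERS])
        labels = np.concatenate([ds.labels[:, i] for i in range(3)])
        rng = np.random.default_rng(seed)
        sel = rng.permutation(len(pooled))[: cfg.train_sites]
        model = build_model(
            ModelConfig(architecture="one_to_one", channels=cfg.model.channels,
                        dense_width=cfg.model.dense_width),
            (8, cfg.window, cfg.depth_rows), seed=seed,
        )
        tc = cfg.train_config(seed)
        train_stage(
            model, pooled[sel], {"sample": labels[sel]},
            tc.stage1_lr, tc.stage1_epochs, tc, alpha=0.0,
        )
        return model

    # -- measurements ---------------------------------------------------------

    def heldout_genotype_calls(self, model: NetworkModel) -> np.ndarray:
        """(3, n_heldout) argmax genotype indices on the held-out split."""
        held = self.data.held_ds
        if model.config.architecture == "one_to_one":
            rows = []
            for m in MEMBERS:
                probs = model.predict_probs(held.sample_block(m))
                rows.append(probs["sample"]["genotype21"].argmax(axis=1))
            return np.stack(rows)
        pred = predict(model, held.tensors)
        return np.stack(
            [pred.p_child.argmax(1), pred.p_parent1.argmax(1), pred.p_parent2.argmax(1)]
        )

    def heldout_violations(self, model: NetworkModel) -> int:
        g = self.heldout_genotype_calls(model)
        return int((MISMATCH_TABLE[g[0], g[1], g[2]] > 0).sum())

    def heldout_f1(self, model: NetworkModel) -> dict:
        """Exact-match per-member F1 on held-out sites, plus the pooled micro F1."""
        with tempfile.TemporaryDirectory() as tmp:
            tmp = Path(tmp)
            truth_paths = write_truth_vcfs(self.data.held_truth, tmp / "truth")
            callset = call_variants(model, self.data.held_ds, self.data.held_truth)
            call_paths = callset.write_vcfs(tmp / "calls")
            out: dict = {}
            tot = {"tp": 0, "fp": 0, "fn": 0}
            for m in MEMBERS:
                sc = score_calls(call_paths[m], truth_paths[m])["overall"]
                out[m] = sc
                for k in tot:
                    tot[k] += sc[k]
        precision = tot["tp"] / max(tot["tp"] + tot["fp"], 1)
        recall = tot["tp"] / max(tot["tp"] + tot["fn"], 1)
        f1 = 2 * precision * recall / max(precision + recall, 1e-12)
        out["pooled"] = {"precision": precision, "recall": recall, "f1": f1}
        return out
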