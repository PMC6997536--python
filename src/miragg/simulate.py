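"""Synthetic multi-source prediction lists with known ground truth.

The generator emulates the statistical structure of real target-prediction
benchmarks at the rank-list level: a universe of miRNA::mRNA interactions of
which a small fraction (5% by default) is "validated", and K divergent
sources that each score a configurable fraction of the universe with a
configurable amount of signal.  Source j's latent score for interaction i is

    q_ij = signal_j * label_i + e_ij,   e_ij ~ Normal(0, 1) i.i.d.

so each source is an independent noisy ranking whose ROC AUC grows
monotonically with ``signal_j`` (signal 0 = uninformative, AUC 1/2).  Which
interactions a source lists is, by default, independent of the label
(uninformative missingness); a biased-coverage option makes validated
interactions more likely to be listed, to probe the behaviour of max-rank
imputation.  Sequence-level features (seed matches, free energy,
conservation) are deliberately not modelled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregation import HIGHER, SourceList

__all__ = ["SimConfig", "SimTruth", "simulate_sources", "make_fixture", "PROFILES"]


@dataclass
class SimConfig:
    """Study conditions for one simulated benchmark.

    ``coverage`` and ``signal`` accept either a scalar (shared by all
    sources) or one value per source.  ``coverage_bias`` > 0 makes validated
    interactions more likely to be among the listed fraction (log-odds
    scale); 0 keeps missingness label-independent.
    """

    n_interactions: int = 10_000
    n_sources: int = 4
    prevalence: float = 0.05
    coverage: float | Sequence[float] = 1.0
    signal: float | Sequence[float] = 1.0
    noise_model: str = "gaussian"  # or "mallows"
    mallows_spread: float = 0.05  # displacement scale, fraction of list length
    coverage_bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interactions < 1 or self.n_sources < 1:
            raise ValueError("need at least one interaction and one source")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must be in (0, 1)")
        if round(self.prevalence * self.n_interactions) < 1:
            raise ValueError("configuration yields no validated interactions")
        if self.noise_model not in ("gaussian", "mallows"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for c in self.coverage_per_source():
            if not (0 < c <= 1):
                raise ValueError("coverage must be in (0, 1]")
        for s in self.signal_per_source():
            if s < 0:
                raise ValueError("signal must be >= 0")

    def _per_source(self, value) -> list[float]:
        if np.isscalar(value):
            return [float(value)] * self.n_sources
        vals = [float(v) for v in value]
        if len(vals) != self.n_sources:
            raise ValueError("per-source parameter length must equal n_sources")
        return vals

    def coverage_per_source(self) -> list[float]:
        return self._per_source(self.coverage)

    def signal_per_source(self) -> list[float]:
        return self._per_source(self.signal)


@dataclass
class SimTruth:
    """Ground truth behind one simulation: labels and latent source quality."""

    items: pd.MultiIndex
    labels: np.ndarray
    latent: np.ndarray  # n_interactions x n_sources

    def label_frame(self) -> pd.DataFrame:
        """Validated pairs as a (mirna, gene) table."""
        frame = self.items.to_frame(index=False)
        return frame[self.labels == 1].reset_index(drop=True)


def _universe(n: int) -> pd.MultiIndex:
    n_genes = max(1, int(math.ceil(math.sqrt(n))))
    n_mirnas = int(math.ceil(n / n_genes))
    mirnas = [f"hsa-miR-{i + 1}" for i in range(n_mirnas)]
    genes = [f"GENE{j + 1:05d}" for j in range(n_genes)]
    pairs = [(mirnas[i // n_genes], genes[i % n_genes]) for i in range(n)]
    return pd.MultiIndex.from_tuples(pairs, names=["mirna", "gene"])


def simulate_sources(config: SimConfig) -> tuple[list[SourceList], SimTruth]:
    """Generate K scored prediction lists over one interaction universe.

    The number of validated interactions is exactly
    ``round(prevalence * n_interactions)`` by stratified construction.
    Raw scores are emitted better-is-higher; the truth (labels and latent
    scores) is returned separately and never leaks into the lists.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_interactions
    items = _universe(n)
    n_pos = int(round(config.prevalence * n))
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    signals = config.signal_per_source()
    coverages = config.coverage_per_source()
    latent = np.empty((n, config.n_sources))
    sources = []
    frame = items.to_frame(index=False)
    for j in range(config.n_sources):
        if config.noise_model == "gaussian":
            q = signals[j] * labels + rng.standard_normal(n)
        else:
            q = _mallows_scores(labels, signals[j], config.mallows_spread, rng)
        latent[:, j] = q
        m = int(round(coverages[j] * n))
        m = max(1, m)
        if m == n and config.coverage_bias == 0:
            listed = np.arange(n)
        else:
            # Gumbel top-m trick == weighted sampling without replacement
            logits = config.coverage_bias * labels + rng.gumbel(size=n)
            listed = np.sort(np.argpartition(-logits, m - 1)[:m])
        entries = frame.iloc[listed].copy()
        entries["score"] = q[listed]
        sources.append(
            SourceList(
                name=f"source{j + 1}",
                entries=entries.reset_index(drop=True),
                direction=HIGHER,
            )
        )
    return sources, SimTruth(items=items, labels=labels, latent=latent)


def _mallows_scores(labels, signal, spread, rng):
    """Rank-perturbation noise: start from the label-perfect order and
    displace each item by a Gaussian number of positions (scaled by
    ``spread`` x list length, shrunk as signal grows)."""
    n = len(labels)
    base = np.argsort(np.argsort(-(labels + rng.uniform(0, 1e-9, n)), kind="mergesort"))
    sigma = spread * n / max(signal, 1e-12)
    perturbed = base + rng.normal(0, sigma, size=n)
    return -perturbed  # higher = better


PROFILES: dict[str, SimConfig] = {
    # small enough to inspect by eye / use in doctests and golden files
    "tiny": SimConfig(n_interactions=100, n_sources=3, prevalence=0.05,
                      coverage=0.8, signal=2.0, seed=7),
    # mirrors the replicate design: 50,000 interactions, 4 sources, 5% validated
    "bench": SimConfig(n_interactions=50_000, n_sources=4, prevalence=0.05,
                       coverage=1.0, signal=1.0, seed=7),
    # the full-scale configuration: one million interactions, 5% validated
    "paper_scale": SimConfig(n_interactions=1_000_000, n_sources=4, prevalence=0.05,
                             coverage=1.0, signal=1.0, seed=7),
}

_TINY_N_PATHWAYS = 5


def make_fixture(profile: str, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Write a complete, self-consistent benchmark fixture to ``out_dir``.

    Emits one TSV per source (mirna, gene, score), a validated-pair TSV, a
    sources config (JSON) declaring each source's direction, and — for the
    ``tiny`` profile — a small GMT file of synthetic pathways partitioning
    the gene universe.  Output is byte-identical across runs for a fixed
    seed.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}")
    config = PROFILES[profile]
    if seed is not None:
        config = SimConfig(**{**config.__dict__, "seed": seed})
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    sources, truth = simulate_sources(config)
    written: dict[str, Path] = {}
    config_entries = []
    for src in sources:
        path = out_dir / f"{src.name}.tsv"
        src.entries.to_csv(path, sep="\t", index=False, float_format="%.9g")
        written[src.name] = path
        config_entries.append({"name": src.name, "path": path.name, "direction": src.direction})

    labels_path = out_dir / "labels.tsv"
    truth.label_frame().to_csv(labels_path, sep="\t", index=False)
    written["labels"] = labels_path

    config_path = out_dir / "sources.json"
    config_path.write_text(json.dumps({"sources": config_entries}, indent=2) + "\n")
    written["config"] = config_path

    if profile == "tiny":
        genes = sorted(set(truth.items.get_level_values("gene")))
        gmt_path = out_dir / "pathways.gmt"
        with open(gmt_path, "w") as fh:
            for p in range(_TINY_N_PATHWAYS):
                members = genes[p::_TINY_N_PATHWAYS]
                fh.write("\t".join([f"PW{p + 1}", f"synthetic pathway {p + 1}"] + members) + "\n")
        written["pathways"] = gmt_path
    return written
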