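"""Synthetic paired NGS / microarray miRNA expression generator.

Model (all latent quantities on the natural-log scale):

* Per-miRNA baseline abundance ``mu_i`` is log-normal: Normal in log space
  with spread ``baseline_log_sd`` (wide — the observed count dynamic range
  spans several orders of magnitude).  Planted differential miRNAs draw
  their baseline from a high-abundance band (``planted_log_mean`` ±
  ``planted_log_sd``): disease-informative miRNAs in this tissue are among
  the most abundant, and the outlier-based feature selection downstream
  relies on that structure.
* Per-(miRNA, sample) biological variation: Normal(0, ``bio_sd``), shared
  by both platforms measuring the same specimen.
* Planted effects add ``log2fc·ln 2`` to tumor columns only.
* NGS counts: negative-binomial (gamma–Poisson) around library-size-scaled
  relative abundances; dispersion ``nb_dispersion`` (Poisson at 0).
* Microarray: probe intensities ``exp(latent + probe offset + noise)``
  with fixed per-probe affinity offsets (``probe_offset_sd``) and
  per-observation noise (``array_noise_sd``), several probes per miRNA.
* Technical replicates: Poisson re-draws around the observed profile with
  a small log-scale jitter (``replicate_noise_sd``).

Every draw is a pure function of (config, seed): independent seeded
streams are derived per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .matrix import ExpressionMatrix, ProbeMap, SampleRecord, SampleTable
from .novel import CandidateCall

__all__ = [
    "GeneratorConfig",
    "LatentMatrix",
    "simulate_latent_expression",
    "simulate_ngs_counts",
    "simulate_microarray_signals",
    "simulate_technical_replicates",
    "simulate_candidate_calls",
    "simulate_sample_table",
    "simulate_dataset",
]

# stream tags so each operation gets an independent reproducible stream
_STREAM_LATENT = 1
_STREAM_COUNTS = 2
_STREAM_ARRAY = 3
_STREAM_REPLICATES = 4
_STREAM_CANDIDATES = 5


def _default_fold_changes(n_diff: int) -> tuple[float, ...]:
    """Mixed-sign log2 fold changes with magnitudes spanning [1.5, 3.5]."""
    if n_diff == 0:
        return ()
    mags = np.linspace(1.5, 3.5, n_diff)
    signs = np.array([1 if i % 2 == 0 else -1 for i in range(n_diff)])
    return tuple(float(v) for v in mags * signs)


@dataclass(frozen=True)
class GeneratorConfig:
    n_mirna: int = 300
    n_tumor: int = 14
    n_control: int = 6
    n_diff: int = 11
    log2_fold_changes: tuple[float, ...] | None = None
    mean_library_size: float = 2.2e6
    mapped_fraction: float = 0.57
    library_size_cv: float = 0.1
    nb_dispersion: float = 0.2
    baseline_log_sd: float = 2.0
    bio_sd: float = 1.0
    planted_log_mean: float = 6.5
    planted_log_sd: float = 0.3
    array_noise_sd: float = 1.2
    probe_offset_sd: float = 3.2
    probes_per_mirna: int = 2
    replicate_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mirna, self.n_tumor, self.n_control) < 1:
            raise ValueError("n_mirna, n_tumor, n_control must be positive")
        if not 0 <= self.n_diff <= self.n_mirna:
            raise ValueError("n_diff must lie in [0, n_mirna]")
        if self.log2_fold_changes is not None and len(self.log2_fold_changes) != self.n_diff:
            raise ValueError("log2_fold_changes length must equal n_diff")
        if self.mean_library_size <= 0 or not 0 < self.mapped_fraction <= 1:
            raise ValueError("invalid library size configuration")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.probes_per_mirna < 1:
            raise ValueError("probes_per_mirna must be >= 1")

    @property
    def fold_changes(self) -> tuple[float, ...]:
        if self.log2_fold_changes is not None:
            return tuple(self.log2_fold_changes)
        return _default_fold_changes(self.n_diff)

    @property
    def assigned_reads(self) -> float:
        """Expected reads assigned to miRNAs per sample (total × mapped)."""
        return self.mean_library_size * self.mapped_fraction

    @property
    def n_samples(self) -> int:
        return self.n_tumor + self.n_control

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class LatentMatrix:
    """True log-scale (natural log) abundances plus the planted truth."""

    values: np.ndarray  # n_mirna × n_samples
    mirna_ids: list[str]
    sample_ids: list[str]
    planted_ids: list[str]
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    tumor_ids: list[str] = field(default_factory=list)
    control_ids: list[str] = field(default_factory=list)


def simulate_sample_table(config: GeneratorConfig) -> SampleTable:
    records = [
        SampleRecord(f"T{i + 1:02d}", "tumor", platforms=frozenset({"ngs", "microarray"}))
        for i in range(config.n_tumor)
    ] + [
        SampleRecord(f"N{i + 1:02d}", "control", platforms=frozenset({"ngs", "microarray"}))
        for i in range(config.n_control)
    ]
    return SampleTable(records)


def simulate_latent_expression(config: GeneratorConfig) -> LatentMatrix:
    """Baseline log-normal abundances plus planted tumor-only shifts."""
    rng = config.rng(_STREAM_LATENT)
    mirna_ids = [f"mir-{i + 1:04d}" for i in range(config.n_mirna)]
    table = simulate_sample_table(config)
    tumor_ids = table.samples_with_label("tumor")
    control_ids = table.samples_with_label("control")
    sample_ids = tumor_ids + control_ids

    mu = rng.normal(0.0, config.baseline_log_sd, size=config.n_mirna)
    planted_idx = np.sort(rng.choice(config.n_mirna, size=config.n_diff, replace=False))
    mu[planted_idx] = rng.normal(config.planted_log_mean, config.planted_log_sd, size=config.n_diff)

    latent = mu[:, None] + rng.normal(0.0, config.bio_sd, size=(config.n_mirna, len(sample_ids)))
    fold_changes = config.fold_changes
    for k, idx in enumerate(planted_idx):
        latent[idx, : config.n_tumor] += fold_changes[k] * np.log(2.0)

    return LatentMatrix(
        values=latent,
        mirna_ids=mirna_ids,
        sample_ids=sample_ids,
        planted_ids=[mirna_ids[i] for i in planted_idx],
        planted_log2fc={mirna_ids[i]: fold_changes[k] for k, i in enumerate(planted_idx)},
        tumor_ids=tumor_ids,
        control_ids=control_ids,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma–Poisson negative binomial; Poisson in the zero-dispersion limit."""
    if dispersion == 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _count_means(latent: LatentMatrix, config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Library-size-scaled expected counts: softmax over miRNAs per sample."""
    rel = np.exp(latent.values - latent.values.max(axis=0, keepdims=True))
    frac = rel / rel.sum(axis=0, keepdims=True)
    cv = config.library_size_cv
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        sizes = config.assigned_reads * rng.lognormal(-(sigma**2) / 2, sigma, size=frac.shape[1])
    else:
        sizes = np.full(frac.shape[1], config.assigned_reads)
    return frac * sizes[None, :]


def simulate_ngs_counts(latent: LatentMatrix, config: GeneratorConfig) -> ExpressionMatrix:
    """Negative-binomial read counts around library-size-scaled abundances."""
    rng = config.rng(_STREAM_COUNTS)
    means = _count_means(latent, config, rng)
    counts = _nb_draw(rng, means, config.nb_dispersion)
    return ExpressionMatrix(
        values=counts.astype(float),
        mirna_ids=list(latent.mirna_ids),
        sample_ids=list(latent.sample_ids),
        platform="ngs",
        scale="raw",
    )


def simulate_microarray_signals(
    latent: LatentMatrix, config: GeneratorConfig
) -> tuple[ExpressionMatrix, ProbeMap]:
    """Positive probe-level intensities with per-probe affinity offsets and
    log-Gaussian noise; returns the probe matrix and its probe → miRNA map."""
    rng = config.rng(_STREAM_ARRAY)
    n, s, k = config.n_mirna, len(latent.sample_ids), config.probes_per_mirna
    probe_ids = [f"{m}_p{j + 1}" for m in latent.mirna_ids for j in range(k)]
    offsets = rng.normal(0.0, config.probe_offset_sd, size=n * k)
    noise = rng.normal(0.0, config.array_noise_sd, size=(n * k, s))
    log_signal = np.repeat(latent.values, k, axis=0) + offsets[:, None] + noise
    pmap = ProbeMap({p: m for m in latent.mirna_ids for p in (f"{m}_p{j + 1}" for j in range(k))})
    matrix = ExpressionMatrix(
        values=np.exp(log_signal),
        mirna_ids=probe_ids,
        sample_ids=list(latent.sample_ids),
        platform="microarray",
        scale="raw",
    )
    return matrix, pmap


def simulate_technical_replicates(
    counts: ExpressionMatrix, config: GeneratorConfig, k: int
) -> list[ExpressionMatrix]:
    """k replicate matrices: Poisson re-draws of the observed profile with a
    small log-scale jitter per entry (replicate_noise_sd)."""
    if k < 2:
        raise ValueError("need k >= 2 replicates")
    if counts.scale != "raw" or counts.platform != "ngs":
        raise ValueError("technical replicates are defined for raw NGS matrices")
    rng = config.rng(_STREAM_REPLICATES)
    sd = config.replicate_noise_sd
    out = []
    for _ in range(k):
        jitter = rng.normal(-(sd**2) / 2, sd, size=counts.values.shape) if sd > 0 else 0.0
        redraw = rng.poisson(counts.values * np.exp(jitter))
        out.append(counts.with_values(redraw.astype(float)))
    return out


def simulate_candidate_calls(config: GeneratorConfig, n_candidates: int) -> list[CandidateCall]:
    """Candidate-call table spanning the filter's decision boundary.

    The first three candidates are constructed to pass, fail the sample
    criterion, and fail the probability criterion respectively; the rest
    are random with probabilities spanning [0, 100].
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    rng = config.rng(_STREAM_CANDIDATES)
    samples = [f"T{i + 1:02d}" for i in range(config.n_tumor)] + [
        f"N{i + 1:02d}" for i in range(config.n_control)
    ]
    calls: list[CandidateCall] = []
    for c in range(n_candidates):
        cid = f"cand-{c + 1:03d}"
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(10_000, 50_000_000))
        coord = f"{chrom}:{start}-{start + 60}:{'+' if rng.random() < 0.5 else '-'}"
        if c == 0:
            chosen = list(rng.choice(samples, size=min(5, len(samples)), replace=False))
            probs = rng.uniform(85.0, 99.0, size=len(chosen))
        elif c == 1 and len(samples) >= 2:
            chosen = list(rng.choice(samples, size=2, replace=False))
            probs = rng.uniform(90.0, 99.0, size=2)
        elif c == 2 and len(samples) >= 6:
            chosen = list(rng.choice(samples, size=6, replace=False))
            probs = rng.uniform(10.0, 70.0, size=6)
        else:
            n_det = int(rng.integers(1, len(samples) + 1))
            chosen = list(rng.choice(samples, size=n_det, replace=False))
            probs = rng.uniform(0.0, 100.0, size=n_det)
        for s, p in zip(chosen, probs):
            calls.append(
                CandidateCall(
                    candidate_id=cid,
                    coordinate=coord,
                    probability=float(p),
                    sample_id=str(s),
                    read_support=int(rng.integers(5, 500)),
                )
            )
    return calls


@dataclass
class SyntheticDataset:
    """Everything one pipeline run needs, generated from a single config."""

    config: GeneratorConfig
    latent: LatentMatrix
    counts: ExpressionMatrix
    probe_signals: ExpressionMatrix
    probe_map: ProbeMap
    samples: SampleTable


def simulate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    latent = simulate_latent_expression(config)
    counts = simulate_ngs_counts(latent, config)
    probes, pmap = simulate_microarray_signals(latent, config)
    return SyntheticDataset(
        config=config,
        latent=latent,
        counts=counts,
        probe_signals=probes,
        probe_map=pmap,
        samples=simulate_sample_table(config),
    )
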