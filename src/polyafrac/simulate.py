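"""Synthetic fractionation-seq experiment generator.

The generative model mirrors an oligo-dT tail-length fractionation
experiment: every transcript carries a population of molecules whose poly(A)
tail lengths follow a gamma law; a stepwise low-salt elution partitions the
molecules into six ordered fractions (soft logistic boundaries at fixed
tail-length breakpoints); each (condition, fraction, replicate) library is
then sequenced to a target depth with gamma-Poisson (negative binomial)
counting noise.  In the active-enzyme condition (``WT``) a designated target
subpopulation receives a mean tail extension ``delta`` and, optionally, a
coupled increase in steady-state abundance; the catalytic-mutant condition
(``mut``) leaves all transcripts at baseline.  External spike-ins are added
in equal amounts to every library and anchor between-library normalization.

Ground truth (which transcripts are targets, which rows are spike-ins) is
returned alongside the counts so that downstream calling can be benchmarked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from .data import FractionCountMatrix

__all__ = [
    "TailModel",
    "FractionationModel",
    "SimConfig",
    "SimulatedExperiment",
    "fraction_probabilities",
    "expected_fraction_profile",
    "make_transcripts",
    "simulate_counts",
    "simulate_experiment",
    "simulate_paired_lines",
    "simulate_lfq_table",
]


@dataclass(frozen=True)
class TailModel:
    """Per-molecule poly(A) tail-length law and the target effect.

    Tail lengths are gamma distributed with fixed shape (right-skewed,
    non-negative, as measured tail-length distributions are).  Targets in
    the WT condition get mean ``baseline_mean + delta`` and total molecule
    count multiplied by ``1 + stability_coupling``.
    """

    baseline_mean: float = 75.0  # nt
    baseline_shape: float = 2.0
    delta: float = 150.0  # nt, applied to targets in WT only
    stability_coupling: float = 0.0
    delta_cv: float = 0.35  # CV of the per-target effect multiplier

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0 or self.baseline_shape <= 0:
            raise ValueError("baseline_mean and baseline_shape must be positive")
        if self.delta < 0 or self.stability_coupling < 0:
            raise ValueError("delta and stability_coupling must be >= 0")
        if self.delta_cv < 0:
            raise ValueError("delta_cv must be >= 0")


@dataclass(frozen=True)
class FractionationModel:
    """Soft ordered partition of tail lengths into elution fractions.

    ``breakpoints`` are the tail-length boundaries (nt) between consecutive
    fractions; ``softness`` is the logistic scale of the boundary blur.
    Fraction 1 collects the shortest tails, fraction ``n_fractions`` the
    longest.
    """

    breakpoints: tuple[float, ...] = (30.0, 60.0, 100.0, 150.0, 220.0)
    softness: float = 10.0

    def __post_init__(self) -> None:
        b = np.asarray(self.breakpoints, float)
        if b.ndim != 1 or len(b) < 1 or np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if self.softness <= 0:
            raise ValueError("softness must be positive")

    @property
    def n_fractions(self) -> int:
        return len(self.breakpoints) + 1


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated fractionation experiment."""

    n_transcripts: int = 2000
    target_fraction: float = 0.1
    replicates: int = 1
    mean_depth: float = 1_000_000.0
    nb_dispersion: float = 0.05
    tail_model: TailModel = field(default_factory=TailModel)
    fractionation: FractionationModel = field(default_factory=FractionationModel)
    n_spikeins: int = 92
    utr_length_bias: float = 1.0
    planted_motif: str | None = None
    abundance_sdlog: float = 0.8
    depth_jitter_sdlog: float = 0.15
    spikein_mass_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_transcripts < 0 or self.n_spikeins < 0:
            raise ValueError("sizes must be non-negative")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError("target_fraction must lie in [0, 1]")
        if self.target_fraction > 0 and self.n_transcripts == 0:
            raise ValueError("target_fraction > 0 requires n_transcripts > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.mean_depth <= 0 or self.nb_dispersion <= 0:
            raise ValueError("mean_depth and nb_dispersion must be positive")
        if self.utr_length_bias <= 0:
            raise ValueError("utr_length_bias must be positive")
        if self.planted_motif is not None:
            if not self.planted_motif or set(self.planted_motif) - set("ACGT"):
                raise ValueError("planted_motif must be a non-empty ACGT string")


@dataclass
class SimulatedExperiment:
    """Counts plus ground truth returned by :func:`simulate_experiment`."""

    counts: FractionCountMatrix
    transcripts: pd.DataFrame  # annotation incl. is_target / is_spikein truth
    tail_model: TailModel
    config: SimConfig


# ---------------------------------------------------------------------------
# fraction allocation
# ---------------------------------------------------------------------------

def fraction_probabilities(tail_length, model: FractionationModel) -> np.ndarray:
    """Probability of a molecule with a given tail length eluting in each fraction.

    Defined as successive differences of logistic CDFs centred at the
    breakpoints: ``P(fraction <= j) = expit((b_j - L) / softness)``.  The
    components are non-negative and sum to 1 exactly; in the ``softness -> 0``
    limit this is the hard partition by breakpoint interval.

    Accepts a scalar or an array of tail lengths; fraction probabilities are
    returned along the last axis.
    """
    L = np.asarray(tail_length, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("tail_length must be finite")
    if np.any(L < 0):
        raise ValueError("tail_length must be >= 0")
    b = np.asarray(model.breakpoints, float)
    cum = expit((b - L[..., None]) / model.softness)
    shape = L.shape + (1,)
    cum = np.concatenate(
        [np.zeros(shape), cum, np.ones(shape)], axis=-1
    )
    p = np.diff(cum, axis=-1)
    if np.isscalar(tail_length) or np.ndim(tail_length) == 0:
        return p[0] if p.ndim > 1 else p
    return p


def expected_fraction_profile(
    mean,
    shape: float,
    model: FractionationModel,
    n_nodes: int = 200,
) -> np.ndarray:
    """Expected fraction allocation of a gamma tail-length population.

    Integrates :func:`fraction_probabilities` against the gamma density with
    the given mean and shape, by Gauss-Legendre quadrature in quantile space
    (the infinite-molecule limit of per-molecule allocation).  ``mean`` may
    be a scalar (returns shape (n_fractions,)) or an array of means
    (returns shape (n_means, n_fractions)).
    """
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (x + 1.0)  # quantiles in (0, 1)
    w = 0.5 * w
    mean_arr = np.atleast_1d(np.asarray(mean, float))
    L = gamma_dist.ppf(u[:, None], a=shape, scale=mean_arr / shape)
    P = fraction_probabilities(L, model)  # (n_nodes, n_means, n_frac)
    profile = np.einsum("n,nmf->mf", w, P)
    profile /= profile.sum(axis=1, keepdims=True)
    if np.ndim(mean) == 0:
        return profile[0]
    return profile


# ---------------------------------------------------------------------------
# transcript annotation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _plant_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Overwrite random positions of ``seq`` with copies of ``motif``."""
    n = len(seq)
    m = len(motif)
    if m > n:
        return seq
    n_copies = max(2, n // 150)
    out = list(seq)
    for _ in range(n_copies):
        start = int(rng.integers(0, n - m + 1))
        out[start : start + m] = motif
    return "".join(out)


def make_transcripts(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the transcript annotation table with ground-truth labels.

    Columns: transcript_id, mrna_length, utr3_length, utr3_seq, abundance
    (relative molecule count), is_target, is_spikein.  Spike-ins carry no
    sequence and are never targets.
    """
    n = config.n_transcripts
    ids = [f"tx{i + 1:05d}" for i in range(n)]
    n_targets = int(round(config.target_fraction * n))
    is_target = np.zeros(n, dtype=bool)
    if n_targets:
        is_target[rng.choice(n, size=n_targets, replace=False)] = True

    mrna_len = np.round(
        np.exp(rng.normal(np.log(2000.0), 0.5, size=n))
    ).astype(int)
    mrna_len = np.clip(mrna_len, 400, 15000)

    utr_len = np.exp(rng.normal(np.log(600.0), 0.6, size=n))
    utr_len[is_target] *= config.utr_length_bias
    utr_len = np.round(utr_len).astype(int)
    utr_len = np.clip(utr_len, 30, mrna_len - 100)

    seqs = []
    for i in range(n):
        s = _random_seq(int(utr_len[i]), rng)
        if config.planted_motif is not None and is_target[i]:
            s = _plant_motif(s, config.planted_motif, rng)
        seqs.append(s)

    abundance = np.exp(rng.normal(0.0, config.abundance_sdlog, size=n))

    # per-target effect-size multiplier: substrates differ in how strongly
    # the enzyme extends them; the stability gain tracks the same multiplier
    cv = config.tail_model.delta_cv
    effect = np.ones(n)
    if cv > 0 and n_targets:
        effect[is_target] = rng.gamma(
            shape=1.0 / cv**2, scale=cv**2, size=n_targets
        )

    df = pd.DataFrame(
        {
            "transcript_id": ids,
            "mrna_length": mrna_len,
            "utr3_length": utr_len,
            "utr3_seq": seqs,
            "abundance": abundance,
            "effect_size": effect,
            "is_target": is_target,
            "is_spikein": False,
        }
    )

    if config.n_spikeins:
        # ERCC-style: fixed known amounts spanning ~4 orders of magnitude
        spike_ab = np.geomspace(1e-2, 1e2, config.n_spikeins)
        mean_pool = abundance.sum() if n else 1.0
        spike_ab *= config.spikein_mass_fraction * mean_pool / spike_ab.sum()
        spikes = pd.DataFrame(
            {
                "transcript_id": [
                    f"spike{j + 1:03d}" for j in range(config.n_spikeins)
                ],
                "mrna_length": 1000,
                "utr3_length": 0,
                "utr3_seq": "",
                "abundance": spike_ab,
                "effect_size": 1.0,
                "is_target": False,
                "is_spikein": True,
            }
        )
        df = pd.concat([df, spikes], ignore_index=True)

    return df.set_index("transcript_id", drop=False)


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _nb_counts(
    mu: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    transcripts: pd.DataFrame, config: SimConfig, seed: int | None = None
) -> FractionCountMatrix:
    """Sequence the annotated transcript pool into fraction libraries.

    Expected per-library counts are compositional: each library's depth is
    split among transcript molecules present in that (condition, fraction)
    pool plus the constant spike-in amounts, then perturbed with negative
    binomial noise.  One RNG sub-stream per library keeps output byte-stable
    under a fixed master seed.
    """
    if seed is None:
        seed = config.seed
    tm, fm = config.tail_model, config.fractionation
    n_frac = fm.n_fractions

    profile_base = expected_fraction_profile(tm.baseline_mean, tm.baseline_shape, fm)

    is_spike = transcripts["is_spikein"].to_numpy()
    is_target = transcripts["is_target"].to_numpy()
    abundance = transcripts["abundance"].to_numpy(float)
    if "effect_size" in transcripts.columns:
        effect = transcripts["effect_size"].to_numpy(float)
    else:
        effect = np.ones(len(transcripts))

    # molecules per (transcript, fraction) for each condition; spike-ins are
    # added per library in fixed amounts, independent of the fractionation
    pools: dict[str, np.ndarray] = {}
    for cond in ("WT", "mut"):
        prof = np.tile(profile_base, (len(transcripts), 1))
        ab = abundance.copy()
        if cond == "WT" and is_target.any():
            means = tm.baseline_mean + tm.delta * effect[is_target]
            prof[is_target] = expected_fraction_profile(
                means, tm.baseline_shape, fm
            )
            ab[is_target] *= 1.0 + tm.stability_coupling * effect[is_target]
        mol = ab[:, None] * prof
        mol[is_spike] = abundance[is_spike, None]  # equal in every library
        pools[cond] = mol

    lib_ids, rows = [], []
    for cond in ("WT", "mut"):
        for f in range(1, n_frac + 1):
            for r in range(1, config.replicates + 1):
                lib_ids.append(f"{cond}_f{f}_r{r}")
                rows.append((cond, f, r))

    master = np.random.SeedSequence(seed)
    lib_seeds = master.spawn(len(lib_ids))

    counts = np.zeros((len(transcripts), len(lib_ids)), dtype=np.int64)
    for j, ((cond, f, _r), ss) in enumerate(zip(rows, lib_seeds)):
        rng = np.random.default_rng(ss)
        pool = pools[cond][:, f - 1]
        total = pool.sum()
        depth = config.mean_depth * np.exp(
            rng.normal(0.0, config.depth_jitter_sdlog)
        )
        mu = depth * pool / total
        counts[:, j] = _nb_counts(mu, config.nb_dispersion, rng)

    count_df = pd.DataFrame(counts, index=transcripts.index, columns=lib_ids)
    samples = pd.DataFrame(
        rows, index=pd.Index(lib_ids, name="library_id"), columns=["condition", "fraction", "replicate"]
    )
    return FractionCountMatrix(
        count_df, samples, transcripts["is_spikein"].copy()
    )


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Generate one full experiment: annotation, counts and ground truth.

    Deterministic: the same config (including its seed) reproduces the
    output exactly.
    """
    master = np.random.SeedSequence(config.seed)
    annot_seed, counts_seed = master.spawn(2)
    transcripts = make_transcripts(config, np.random.default_rng(annot_seed))
    counts = simulate_counts(
        transcripts, config, seed=counts_seed.generate_state(1)[0] % (2**31)
    )
    return SimulatedExperiment(counts, transcripts, config.tail_model, config)


def simulate_paired_lines(
    config: SimConfig,
    shared_target_fraction: float = 0.6,
    seed: int | None = None,
) -> tuple[SimulatedExperiment, SimulatedExperiment]:
    """Two "cell lines" over one transcriptome whose true target sets overlap.

    Line B's target set keeps ``shared_target_fraction`` of line A's targets
    and draws the remainder from non-targets, so the planned overlap
    fraction |A & B| / |B| equals ``shared_target_fraction``.  Counts for the
    two lines are simulated independently.
    """
    if seed is None:
        seed = config.seed
    master = np.random.SeedSequence(seed)
    ss_annot, ss_pick, ss_a, ss_b = master.spawn(4)

    transcripts_a = make_transcripts(config, np.random.default_rng(ss_annot))
    rng = np.random.default_rng(ss_pick)

    targets_a = np.flatnonzero(transcripts_a["is_target"].to_numpy())
    eligible = np.flatnonzero(
        ~transcripts_a["is_target"].to_numpy()
        & ~transcripts_a["is_spikein"].to_numpy()
    )
    n_keep = int(round(shared_target_fraction * len(targets_a)))
    keep = rng.choice(targets_a, size=n_keep, replace=False)
    fresh = rng.choice(eligible, size=len(targets_a) - n_keep, replace=False)

    transcripts_b = transcripts_a.copy()
    is_target_b = np.zeros(len(transcripts_b), dtype=bool)
    is_target_b[keep] = True
    is_target_b[fresh] = True
    transcripts_b["is_target"] = is_target_b

    counts_a = simulate_counts(
        transcripts_a, config, seed=ss_a.generate_state(1)[0] % (2**31)
    )
    counts_b = simulate_counts(
        transcripts_b, config, seed=ss_b.generate_state(1)[0] % (2**31)
    )
    return (
        SimulatedExperiment(counts_a, transcripts_a, config.tail_model, config),
        SimulatedExperiment(counts_b, transcripts_b, config.tail_model, config),
    )


# ---------------------------------------------------------------------------
# Co-IP LFQ fixture generator
# ---------------------------------------------------------------------------

def simulate_lfq_table(
    n_proteins: int,
    n_enriched: int,
    seed: int,
    n_bait_runs: int = 3,
    n_control_runs: int = 3,
    n_contaminants: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label-free quantification table with known enriched interactors.

    Non-enriched proteins draw bait and control intensities from one
    log-normal law (with random per-run dropout); enriched proteins are
    either bait-only or carry a large bait/control ratio.  Returns the LFQ
    table (protein_id, mw_kda, one column per run, plus ground-truth columns
    ``is_enriched`` and ``is_contaminant``) and the run sheet mapping run
    ids to the bait or control arm.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must be <= n_proteins")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    rng = np.random.default_rng(seed)
    if n_contaminants is None:
        n_contaminants = max(1, n_proteins // 20)
    n_contaminants = min(n_contaminants, n_proteins - n_enriched)

    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    mw = np.clip(np.exp(rng.normal(np.log(50.0), 0.5, size=n_proteins)), 5.0, None)
    base = np.exp(rng.normal(np.log(1e8), 1.0, size=n_proteins))

    is_enriched = np.zeros(n_proteins, dtype=bool)
    if n_enriched:
        is_enriched[rng.choice(n_proteins, size=n_enriched, replace=False)] = True
    is_contaminant = np.zeros(n_proteins, dtype=bool)
    non_enriched = np.flatnonzero(~is_enriched)
    if n_contaminants:
        is_contaminant[rng.choice(non_enriched, size=n_contaminants, replace=False)] = True

    bait_cols = [f"bait_{r + 1}" for r in range(n_bait_runs)]
    ctrl_cols = [f"ctrl_{r + 1}" for r in range(n_control_runs)]

    def draw_runs(n_runs: int, dropout: float, scale: np.ndarray) -> np.ndarray:
        vals = scale[:, None] * np.exp(
            rng.normal(0.0, 0.3, size=(n_proteins, n_runs))
        )
        vals[rng.random((n_proteins, n_runs)) < dropout] = 0.0
        return vals

    bait = draw_runs(n_bait_runs, dropout=0.05, scale=base)
    ctrl = draw_runs(n_control_runs, dropout=0.10, scale=base)

    if n_enriched:
        enr = np.flatnonzero(is_enriched)
        fold = np.exp(rng.normal(np.log(30.0), 0.5, size=len(enr)))
        bait[enr] *= fold[:, None]
        bait_only = rng.random(len(enr)) < 0.5
        ctrl[enr[bait_only]] = 0.0

    table = pd.DataFrame(
        {"protein_id": ids, "mw_kda": mw}, index=pd.Index(ids, name="protein_id")
    )
    for c, col in zip(bait_cols, bait.T):
        table[c] = col
    for c, col in zip(ctrl_cols, ctrl.T):
        table[c] = col
    table["is_enriched"] = is_enriched
    table["is_contaminant"] = is_contaminant

    runs = pd.DataFrame(
        {"run_id": bait_cols + ctrl_cols,
         "arm": ["bait"] * n_bait_runs + ["control"] * n_control_runs}
    ).set_index("run_id")
    return table, runs
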