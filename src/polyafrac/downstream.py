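"""Downstream characterisation of called substrate sets.

Covers four analyses that follow hit calling: concordance of hit sets
between experiments (Venn-style overlap with a hypergeometric test),
length-bias testing of hit 3'-UTR / mRNA lengths (permutation test),
exhaustive k-mer enrichment in hit 3'-UTRs against an expressed-background
set (label-permutation p-values, reported in the RNA alphabet), and the
coupling between polyadenylation and steady-state expression (Spearman).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import _bh_adjust

__all__ = [
    "HitSetComparison",
    "LengthBiasResult",
    "CouplingResult",
    "compare_hit_sets",
    "length_bias_test",
    "kmer_enrichment",
    "expression_coupling",
    "label_enrichment",
]


# ---------------------------------------------------------------------------
# hit-set concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HitSetComparison:
    n_A: int
    n_B: int
    n_overlap: int
    n_universe: int
    jaccard: float
    overlap_fraction_of_B: float
    hypergeometric_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def compare_hit_sets(hits_A, hits_B, universe) -> HitSetComparison:
    """Overlap statistics for two hit sets drawn from one universe.

    The p-value is the hypergeometric upper tail: probability of an overlap
    at least as large as observed when |B| items are drawn uniformly from
    the universe, |A| of which are marked.
    """
    A, B, U = set(hits_A), set(hits_B), set(universe)
    stray = sorted((A | B) - U)
    if stray:
        raise ValueError(f"hits not in universe: {stray}")
    n_a, n_b, n_u = len(A), len(B), len(U)
    n_ov = len(A & B)
    union = n_a + n_b - n_ov
    jaccard = n_ov / union if union else 1.0
    frac_b = n_ov / n_b if n_b else float("nan")
    p = float(stats.hypergeom.sf(n_ov - 1, n_u, n_a, n_b))
    return HitSetComparison(n_a, n_b, n_ov, n_u, jaccard, frac_b, p)


# ---------------------------------------------------------------------------
# length bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LengthBiasResult:
    feature: str
    median_difference: float
    p_value: float
    n_hits: int
    n_background: int
    n_perm: int


def length_bias_test(
    hits,
    annotation: pd.DataFrame,
    feature: str = "utr3_length",
    n_perm: int = 1000,
    seed: int = 0,
) -> LengthBiasResult:
    """Are hit transcripts biased towards shorter features?

    Statistic: median feature of hits minus median of non-hits.  The
    left-tail permutation p-value resamples same-size hit sets from the
    annotated transcripts, with +1 smoothing so p >= 1/(n_perm + 1).
    """
    if feature not in annotation.columns:
        raise ValueError(f"annotation lacks feature column {feature!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    hits = pd.Index(hits)
    values = annotation[feature].astype(float)
    missing = hits.difference(values.index)
    if len(missing):
        raise ValueError(f"hits missing from annotation: {sorted(missing)}")
    m = len(hits)
    if m == 0:
        raise ValueError("empty hit set")
    if m >= len(values):
        raise ValueError("hit set must be a strict subset of annotated transcripts")

    is_hit = values.index.isin(hits)
    arr = values.to_numpy()
    observed = float(np.median(arr[is_hit]) - np.median(arr[~is_hit]))

    rng = np.random.default_rng(seed)
    n = len(arr)
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=m, replace=False)
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        stat = np.median(arr[mask]) - np.median(arr[~mask])
        if stat <= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return LengthBiasResult(feature, observed, p, m, n - m, n_perm)


# ---------------------------------------------------------------------------
# k-mer enrichment
# ---------------------------------------------------------------------------

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _kmer_count_matrix(seqs: list[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Overlapping k-mer occurrence counts per sequence.

    Returns (counts (n_seq, 4^k), windows (n_seq,)).  Sequences must be
    ACGT-only and at least k long.
    """
    n_kmers = 4**k
    weights = 4 ** np.arange(k - 1, -1, -1)
    counts = np.zeros((len(seqs), n_kmers), dtype=np.int64)
    windows = np.zeros(len(seqs), dtype=np.int64)
    for i, seq in enumerate(seqs):
        arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if np.any(arr < 0):
            raise ValueError(f"sequence {i} contains non-ACGT characters")
        if len(arr) < k:
            raise ValueError(f"sequence {i} shorter than k={k}")
        windows[i] = len(arr) - k + 1
        codes = np.lib.stride_tricks.sliding_window_view(arr, k) @ weights
        counts[i] = np.bincount(codes, minlength=n_kmers)
    return counts, windows


def _index_to_kmer(idx: int, k: int, alphabet: str = "ACGU") -> str:
    out = []
    for _ in range(k):
        out.append(alphabet[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def kmer_enrichment(
    fg_utrs,
    bg_utrs,
    k: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Exhaustive k-mer enrichment of foreground UTRs over background.

    Frequencies are overlapping occurrences per window position, pooled
    over each sequence set with a +``pseudocount`` occurrence smoothing.
    One-sided p-values come from permuting sequence labels between the
    foreground and background pools; q is the BH adjustment over all 4^k
    k-mers.  K-mers are reported in the RNA alphabet (U for T).

    Foreground sequences also present in the background are fine (the
    background may be "all expressed transcripts").
    """
    fg = [str(s) for s in fg_utrs]
    bg = [str(s) for s in bg_utrs]
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    shortest = min(len(s) for s in fg + bg)
    if k > shortest:
        raise ValueError(f"k={k} exceeds shortest sequence length {shortest}")

    seqs = fg + bg
    counts, windows = _kmer_count_matrix(seqs, k)
    n_fg = len(fg)
    n = len(seqs)
    n_kmers = 4**k

    def log2_enr(fg_counts, fg_windows, bg_counts, bg_windows):
        f = (fg_counts + pseudocount) / (fg_windows + pseudocount * n_kmers)
        b = (bg_counts + pseudocount) / (bg_windows + pseudocount * n_kmers)
        return np.log2(f / b), f, b

    total_counts = counts.sum(axis=0)
    total_windows = windows.sum()
    obs_fg_counts = counts[:n_fg].sum(axis=0)
    obs_fg_windows = windows[:n_fg].sum()
    observed, fg_freq, bg_freq = log2_enr(
        obs_fg_counts,
        obs_fg_windows,
        total_counts - obs_fg_counts,
        total_windows - obs_fg_windows,
    )

    rng = np.random.default_rng(seed)
    exceed = np.zeros(n_kmers, dtype=np.int64)
    for _ in range(n_perm):
        idx = rng.choice(n, size=n_fg, replace=False)
        fg_c = counts[idx].sum(axis=0)
        fg_w = windows[idx].sum()
        stat, _, _ = log2_enr(fg_c, fg_w, total_counts - fg_c, total_windows - fg_w)
        exceed += stat >= observed
    p = (exceed + 1) / (n_perm + 1)
    q = _bh_adjust(p)

    out = pd.DataFrame(
        {
            "kmer": [_index_to_kmer(i, k) for i in range(n_kmers)],
            "fg_freq": fg_freq,
            "bg_freq": bg_freq,
            "log2_enrichment": observed,
            "p": p,
            "q": q,
        }
    )
    return out.sort_values(
        "log2_enrichment", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# polyadenylation <-> expression coupling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingResult:
    rho: float
    p_value: float
    n_hits: int
    reliable: bool


def expression_coupling(
    ratio_table: pd.DataFrame,
    expression_log2fc: pd.Series,
    min_hits: int = 10,
) -> CouplingResult:
    """Spearman correlation between hit log2 ratios and expression change.

    Restricted to combined hits; the ratio statistic is the mean log2 ratio
    over the long fractions.  With fewer than ``min_hits`` hits the result
    is returned flagged unreliable (with a warning) rather than raising.
    """
    shared = ratio_table.index.intersection(expression_log2fc.index)
    if len(shared) == 0:
        raise ValueError("no shared transcript ids")
    t = ratio_table.loc[shared]
    hits = t.index[t["combined_hit"]]
    ratio_cols = [c for c in t.columns if c.startswith("log2_ratio_f")]
    x = t.loc[hits, ratio_cols].mean(axis=1)
    y = expression_log2fc.loc[hits]
    reliable = len(hits) >= min_hits
    if len(hits) < 2:
        warnings.warn("fewer than 2 combined hits; coupling undefined")
        return CouplingResult(float("nan"), float("nan"), len(hits), False)
    if not reliable:
        warnings.warn(
            f"only {len(hits)} combined hits (< {min_hits}); "
            "coupling estimate flagged unreliable"
        )
    rho, p = stats.spearmanr(x, y)
    return CouplingResult(float(rho), float(p), int(len(hits)), bool(reliable))


# ---------------------------------------------------------------------------
# label enrichment (functional-annotation stand-in)
# ---------------------------------------------------------------------------

def label_enrichment(hits, labels: pd.Series, universe) -> HitSetComparison:
    """Hypergeometric enrichment of a boolean transcript label among hits.

    A generic stand-in for functional-annotation clustering: ``labels``
    flags e.g. secretory-pathway transcripts; the test asks whether hits
    are overrepresented among the labelled set.
    """
    labelled = labels.index[labels.astype(bool)]
    return compare_hit_sets(hits, labelled, universe)
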