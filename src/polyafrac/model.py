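"""Polyadenylation-shift statistic: ratios, robust null, hit calling.

The per-transcript statistic is a ratio of ratios.  For a long fraction
k (5 or 6), with replicate-averaged normalized counts n:

    R_k = [ (n_k + a) / (n_1 + a) ]_WT  /  [ (n_k + a) / (n_1 + a) ]_mut

reported as log2(R_k), where fraction 1 holds the shortest tails and ``a``
is a pseudocount.  For the bulk of transcripts the enzyme has no effect and
log2 R_k scatters around zero; substrates form a right-tail outlier
population.  A normal null is therefore fitted robustly (median location,
1.4826 x MAD scale) so the outliers do not inflate it, one-sided right-tail
p-values are taken against it, and Benjamini-Hochberg adjustment is applied
within each fraction.  A transcript is a combined hit when it is significant
in BOTH long fractions and passes a minimum-expression filter on its
short-fraction abundance.

The public surface follows the Model/Results convention:

>>> model = PolyadenylationShiftModel(counts)          # doctest: +SKIP
>>> res = model.fit(q_threshold=0.05)                  # doctest: +SKIP
>>> res.summary()                                      # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import FractionCountMatrix

__all__ = [
    "NormalizedCounts",
    "NullModel",
    "DegenerateNullError",
    "normalize",
    "polyadenylation_ratio",
    "fit_null",
    "call_hits",
    "PolyadenylationShiftModel",
    "PolyadenylationShiftResults",
]


class DegenerateNullError(ValueError):
    """Raised when the log-ratio distribution has zero robust scale."""


@dataclass
class NormalizedCounts:
    """Library-normalized counts with the size factors that produced them."""

    values: pd.DataFrame
    size_factors: pd.Series
    mode: str  # "spikein" or "total"


@dataclass(frozen=True)
class NullModel:
    """Robust normal null over log2 polyadenylation ratios."""

    mu: float
    sigma: float
    method: str = "median-MAD"
    n_used: int = 0

    def zscore(self, x):
        return (np.asarray(x, float) - self.mu) / self.sigma


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize(data: FractionCountMatrix, mode: str = "auto") -> NormalizedCounts:
    """Divide each library by a size factor with geometric mean 1.

    ``spikein`` mode sums the spike-in rows per library (spike-ins are added
    in equal amounts to every library, so their totals are the only
    fraction-independent anchor); ``total`` sums all rows; ``auto`` picks
    spike-in normalization whenever at least 3 spike-in rows are present.
    """
    if mode not in ("auto", "spikein", "total"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    n_spikes = int(data.spikein.sum())
    if mode == "auto":
        mode = "spikein" if n_spikes >= 3 else "total"
    if mode == "spikein":
        if n_spikes < 3:
            raise ValueError(
                f"spikein normalization needs >= 3 spike-in rows, found {n_spikes}"
            )
        sums = data.counts.loc[data.spikein].sum(axis=0)
    else:
        sums = data.counts.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValueError(
            f"zero {mode} count sum in libraries: {list(zero)}"
        )
    log_sums = np.log(sums.astype(float))
    factors = np.exp(log_sums - log_sums.mean())  # geometric mean 1
    values = data.counts.astype(float).div(factors, axis=1)
    return NormalizedCounts(values, factors, mode)


# ---------------------------------------------------------------------------
# ratio statistic
# ---------------------------------------------------------------------------

def _condition_fraction_mean(
    norm: NormalizedCounts, data: FractionCountMatrix, condition: str, fraction: int
) -> pd.Series:
    libs = data.libraries(condition=condition, fraction=fraction)
    if not libs:
        raise ValueError(f"no libraries for condition={condition}, fraction={fraction}")
    return norm.values[libs].mean(axis=1)


def polyadenylation_ratio(
    norm: NormalizedCounts,
    data: FractionCountMatrix,
    k: int,
    pseudocount: float = 0.5,
    reference_fraction: int = 1,
) -> pd.Series:
    """Per-transcript log2 ratio-of-ratios for long fraction ``k``.

    Replicates are averaged (arithmetic mean of normalized counts) before
    the ratio is formed.  With pseudocount 0 a zero denominator yields NaN
    for that transcript (undefined, not an error).  Spike-in rows are
    excluded from the returned Series.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    a = pseudocount
    nk_wt = _condition_fraction_mean(norm, data, "WT", k)
    n1_wt = _condition_fraction_mean(norm, data, "WT", reference_fraction)
    nk_mut = _condition_fraction_mean(norm, data, "mut", k)
    n1_mut = _condition_fraction_mean(norm, data, "mut", reference_fraction)
    # computed as a difference of log-ratios so that swapping the condition
    # labels negates the statistic bit-exactly
    with np.errstate(divide="ignore", invalid="ignore"):
        wt_term = np.log2(nk_wt + a) - np.log2(n1_wt + a)
        mut_term = np.log2(nk_mut + a) - np.log2(n1_mut + a)
        log2r = wt_term - mut_term
    log2r = log2r.replace([np.inf, -np.inf], np.nan)
    keep = ~data.spikein.reindex(log2r.index, fill_value=False)
    out = log2r[keep]
    out.name = f"log2_ratio_f{k}"
    return out


# ---------------------------------------------------------------------------
# null fit
# ---------------------------------------------------------------------------

def fit_null(log_ratios) -> NullModel:
    """Fit the normal null robustly: mu = median, sigma = 1.4826 x MAD.

    Robust moments keep the right-tail substrate population from inflating
    the null scale.  Requires at least 3 finite values; a zero MAD
    (effectively constant input) raises :class:`DegenerateNullError`.
    """
    x = np.asarray(pd.Series(log_ratios).dropna(), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError(f"need >= 3 finite log-ratios, got {x.size}")
    mu = float(np.median(x))
    mad = float(np.median(np.abs(x - mu)))
    if mad == 0.0:
        raise DegenerateNullError("MAD of log-ratios is zero; null scale undefined")
    return NullModel(mu=mu, sigma=1.4826 * mad, n_used=int(x.size))


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values; NaNs propagate."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_hits(
    log_ratios: dict[int, pd.Series],
    nulls: dict[int, NullModel],
    q_threshold: float = 0.05,
    expression_filter_min: float = 10.0,
    expression_reference: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-transcript hit table across long fractions.

    For each fraction k: z = (log2 ratio - mu_k) / sigma_k, one-sided
    right-tail normal p, BH q within the fraction, hit_k <=> q <= threshold.
    ``expression_reference`` is the mean normalized short-fraction count
    across conditions; transcripts below ``expression_filter_min`` fail the
    expression filter.  combined_hit <=> significant in every long fraction
    AND expression_pass.
    """
    if q_threshold <= 0 or expression_filter_min < 0:
        raise ValueError("thresholds must be positive")
    ks = sorted(log_ratios)
    idx = log_ratios[ks[0]].index
    for k in ks[1:]:
        if not log_ratios[k].index.equals(idx):
            raise ValueError(
                f"transcript sets differ between fractions {ks[0]} and {k}"
            )
    table = pd.DataFrame(index=idx)
    hit_cols = []
    for k in ks:
        lr = log_ratios[k]
        null = nulls[k]
        z = null.zscore(lr.to_numpy())
        p = stats.norm.sf(z)
        q = _bh_adjust(p)
        table[f"log2_ratio_f{k}"] = lr
        table[f"z_f{k}"] = z
        table[f"p_f{k}"] = p
        table[f"q_f{k}"] = q
        table[f"hit_f{k}"] = pd.Series(q, index=idx) <= q_threshold
        hit_cols.append(f"hit_f{k}")
    if expression_reference is not None:
        expr = expression_reference.reindex(idx)
        table["expression_pass"] = expr >= expression_filter_min
    else:
        table["expression_pass"] = True
    table["combined_hit"] = table[hit_cols].all(axis=1) & table["expression_pass"]
    return table


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PolyadenylationShiftModel:
    """Identify transcripts shifting into long poly(A) fractions.

    Parameters
    ----------
    data
        The fraction count matrix (with sample sheet and spike-in flags).
    long_fractions
        Fractions treated as "long poly(A)"; a combined hit must be
        significant in all of them.
    reference_fraction
        The short-tail reference fraction (denominator of the ratio).
    pseudocount
        Added to every numerator and denominator count; keeps ratios finite.
    normalization
        "spikein", "total" or "auto" (spike-in when >= 3 spike-in rows).
    """

    def __init__(
        self,
        data: FractionCountMatrix,
        long_fractions: tuple[int, ...] = (5, 6),
        reference_fraction: int = 1,
        pseudocount: float = 0.5,
        normalization: str = "auto",
    ):
        self.data = data
        self.long_fractions = tuple(long_fractions)
        self.reference_fraction = reference_fraction
        self.pseudocount = pseudocount
        self.normalization = normalization
        available = set(data.samples.loc[list(data.counts.columns), "fraction"])
        needed = set(self.long_fractions) | {reference_fraction}
        missing = sorted(needed - available)
        if missing:
            raise ValueError(f"count matrix lacks fractions {missing}")

    @classmethod
    def from_tsv(cls, counts_path, samples_path, **kwargs) -> "PolyadenylationShiftModel":
        from .io import read_counts

        return cls(read_counts(counts_path, samples_path), **kwargs)

    def fit(
        self, q_threshold: float = 0.05, min_expression: float = 10.0
    ) -> "PolyadenylationShiftResults":
        norm = normalize(self.data, self.normalization)
        ratios = {
            k: polyadenylation_ratio(
                norm, self.data, k, self.pseudocount, self.reference_fraction
            )
            for k in self.long_fractions
        }
        nulls = {k: fit_null(r) for k, r in ratios.items()}
        expr_ref = (
            pd.concat(
                [
                    _condition_fraction_mean(norm, self.data, c, self.reference_fraction)
                    for c in ("WT", "mut")
                ],
                axis=1,
            )
            .mean(axis=1)
            .reindex(ratios[self.long_fractions[0]].index)
        )
        table = call_hits(
            ratios, nulls, q_threshold, min_expression, expression_reference=expr_ref
        )
        return PolyadenylationShiftResults(
            model=self,
            ratio_table=table,
            null_models=nulls,
            normalized=norm,
            q_threshold=q_threshold,
            min_expression=min_expression,
        )


class PolyadenylationShiftResults:
    """Fitted ratio table, null models and hit calls.

    Attributes
    ----------
    ratio_table : DataFrame
        Per transcript: log2_ratio_fK, z_fK, p_fK, q_fK, hit_fK for each
        long fraction K, plus expression_pass and combined_hit.
    null_models : dict[int, NullModel]
    normalized : NormalizedCounts
    """

    def __init__(self, model, ratio_table, null_models, normalized, q_threshold, min_expression):
        self.model = model
        self.ratio_table = ratio_table
        self.null_models = null_models
        self.normalized = normalized
        self.q_threshold = q_threshold
        self.min_expression = min_expression

    @property
    def hits(self) -> pd.Index:
        """Transcripts significant in all long fractions and expressed."""
        return self.ratio_table.index[self.ratio_table["combined_hit"]]

    def log2_ratio(self, k: int | None = None) -> pd.Series:
        """Log2 ratio for fraction k, or the mean over long fractions."""
        if k is not None:
            return self.ratio_table[f"log2_ratio_f{k}"]
        cols = [f"log2_ratio_f{k}" for k in self.model.long_fractions]
        return self.ratio_table[cols].mean(axis=1)

    def expression_log2fc(self, pseudocount: float | None = None) -> pd.Series:
        """Total-expression log2 fold change (WT vs mut) per transcript.

        Computed from normalized counts summed across all fractions and
        averaged over replicates within a condition.
        """
        a = self.model.pseudocount if pseudocount is None else pseudocount
        data, norm = self.model.data, self.normalized
        totals = {}
        for cond in ("WT", "mut"):
            libs = data.libraries(condition=cond)
            per_rep = norm.values[libs]
            # sum across fractions, mean across replicates
            n_rep = data.samples.loc[libs, "replicate"].nunique()
            totals[cond] = per_rep.sum(axis=1) / n_rep
        lfc = np.log2((totals["WT"] + a) / (totals["mut"] + a))
        return lfc.reindex(self.ratio_table.index)

    def summary(self) -> str:
        t = self.ratio_table
        lines = [
            "Polyadenylation shift analysis",
            "=" * 46,
            f"transcripts analysed : {len(t)}",
            f"normalization        : {self.normalized.mode}",
            f"pseudocount          : {self.model.pseudocount}",
            f"q threshold (BH)     : {self.q_threshold}",
            f"min expression (f{self.model.reference_fraction})  : {self.min_expression}",
        ]
        for k in self.model.long_fractions:
            null = self.null_models[k]
            lines.append(
                f"fraction {k} null      : mu={null.mu:+.4f} sigma={null.sigma:.4f} "
                f"(n={null.n_used}); hits={int(t[f'hit_f{k}'].sum())}"
            )
        lines.append(f"expression pass      : {int(t['expression_pass'].sum())}")
        lines.append(f"combined hits        : {int(t['combined_hit'].sum())}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PolyadenylationShiftResults: {len(self.ratio_table)} transcripts, "
            f"{int(self.ratio_table['combined_hit'].sum())} combined hits>"
        )

    # -- plotting ---------------------------------------------------------
    def plot_ratio_histogram(self, k: int, ax=None, bins: int = 80):
        """Histogram of log2 ratios for fraction k with the fitted null overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.ratio_table[f"log2_ratio_f{k}"].dropna().to_numpy()
        null = self.null_models[k]
        ax.hist(x, bins=bins, density=True, color="0.7", edgecolor="none")
        grid = np.linspace(x.min(), x.max(), 400)
        ax.plot(grid, stats.norm.pdf(grid, null.mu, null.sigma), color="red", lw=1.5)
        ax.set_xlabel(f"log2 polyadenylation ratio (fraction {k})")
        ax.set_ylabel("density")
        return ax

    def histogram_data(self, k: int, bins: int = 80) -> pd.DataFrame:
        """Binned histogram plus fitted-null density, as plain data for export."""
        x = self.ratio_table[f"log2_ratio_f{k}"].dropna().to_numpy()
        hist, edges = np.histogram(x, bins=bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        null = self.null_models[k]
        return pd.DataFrame(
            {
                "bin_center": centers,
                "density": hist,
                "null_density": stats.norm.pdf(centers, null.mu, null.sigma),
            }
        )

    # -- export -----------------------------------------------------------
    def to_dir(self, out_dir, provenance: str | None = None) -> None:
        """Write ratio table TSV, null-model JSON and histogram TSVs."""
        from .io import write_table

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(
            self.ratio_table.rename_axis("transcript_id").reset_index(),
            out / "ratio_table.tsv",
            provenance,
        )
        nulls = {
            str(k): {"mu": n.mu, "sigma": n.sigma, "method": n.method, "n_used": n.n_used}
            for k, n in self.null_models.items()
        }
        (out / "null_models.json").write_text(json.dumps(nulls, indent=2) + "\n")
        for k in self.model.long_fractions:
            write_table(
                self.histogram_data(k), out / f"histogram_f{k}.tsv", provenance
            )
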