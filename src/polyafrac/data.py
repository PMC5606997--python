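"""Core in-memory containers for fractionation-seq data.

A fractionation experiment separates mRNA molecules by poly(A) tail length
into ordered fractions (1 = shortest tails, 6 = longest) for two conditions
(an active enzyme, ``WT``, and its catalytic mutant, ``mut``).  Each
(condition, fraction, replicate) triple is sequenced as one library; the
count matrix is transcripts x libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("WT", "mut")

SAMPLE_COLUMNS = ("condition", "fraction", "replicate")


class DataValidationError(ValueError):
    """Raised when counts or metadata violate the container contract."""


@dataclass
class FractionCountMatrix:
    """Raw sequencing counts indexed by transcript and library.

    Parameters
    ----------
    counts
        Non-negative integer DataFrame, rows = transcript ids (including
        spike-ins), columns = library ids.
    samples
        Sample sheet indexed by library id with columns ``condition``
        (``WT``/``mut``), ``fraction`` (1..n_fractions) and ``replicate``.
    spikein
        Boolean Series over the transcript index flagging spike-in rows.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    spikein: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.spikein is None:
            self.spikein = pd.Series(False, index=self.counts.index)
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        counts, samples = self.counts, self.samples
        missing_cols = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
        if missing_cols:
            raise DataValidationError(f"sample sheet lacks columns {missing_cols}")
        uncovered = [lib for lib in counts.columns if lib not in samples.index]
        if uncovered:
            raise DataValidationError(
                f"libraries missing from sample sheet: {uncovered}"
            )
        bad_cond = sorted(set(samples["condition"]) - set(CONDITIONS))
        if bad_cond:
            raise DataValidationError(f"unknown condition labels: {bad_cond}")
        frac = samples["fraction"]
        if not np.issubdtype(np.asarray(frac).dtype, np.integer):
            raise DataValidationError("fraction labels must be integers")
        if (frac < 1).any():
            raise DataValidationError("fraction labels must be >= 1")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            # allow float storage of integral values (e.g. after TSV round-trip)
            if not np.all(np.isfinite(arr)) or np.any(arr != np.floor(arr)):
                i, j = np.argwhere(~(np.isfinite(arr) & (arr == np.floor(arr))))[0]
                raise DataValidationError(
                    f"non-integer count at transcript {counts.index[i]!r}, "
                    f"library {counts.columns[j]!r}"
                )
            self.counts = counts = counts.astype(np.int64)
            arr = counts.to_numpy()
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise DataValidationError(
                f"negative count at transcript {counts.index[i]!r}, "
                f"library {counts.columns[j]!r}"
            )
        if not self.spikein.index.equals(counts.index):
            self.spikein = self.spikein.reindex(counts.index, fill_value=False)

    # -- convenience ------------------------------------------------------
    @property
    def n_fractions(self) -> int:
        return int(self.samples["fraction"].max())

    @property
    def transcripts(self) -> pd.Index:
        """Non-spike-in transcript ids."""
        return self.counts.index[~self.spikein.to_numpy()]

    def libraries(self, condition: str | None = None, fraction: int | None = None) -> list[str]:
        """Library ids restricted to the count matrix, optionally filtered."""
        s = self.samples.loc[list(self.counts.columns)]
        if condition is not None:
            s = s[s["condition"] == condition]
        if fraction is not None:
            s = s[s["fraction"] == fraction]
        return list(s.index)

    def swap_conditions(self) -> "FractionCountMatrix":
        """Return a copy with WT and mut labels exchanged (antisymmetry checks)."""
        samples = self.samples.copy()
        samples["condition"] = samples["condition"].map({"WT": "mut", "mut": "WT"})
        return FractionCountMatrix(self.counts.copy(), samples, self.spikein.copy())
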