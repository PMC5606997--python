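"""Readers and writers for the plain-text interchange formats.

Everything is tab-separated UTF-8 text (counts, sample sheets, annotation,
LFQ tables), FASTA for UTR sequences and JSON for small result objects.
Output tables carry a single ``#``-prefixed provenance header line (package
version, seed, config hash); all readers skip ``#`` lines.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .data import DataValidationError, FractionCountMatrix

__all__ = [
    "provenance_line",
    "write_table",
    "read_table",
    "write_experiment",
    "read_counts",
    "read_annotation",
    "write_fasta",
    "read_fasta",
    "read_lfq",
]


def provenance_line(seed=None, config: dict | None = None) -> str:
    """One-line run provenance: version, seed and a config digest."""
    parts = [f"polyafrac={__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]
        parts.append(f"config_sha={digest}")
    return "# " + " ".join(parts)


def write_table(df: pd.DataFrame, path, provenance: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(provenance.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# fractionation experiment
# ---------------------------------------------------------------------------

def write_experiment(experiment, out_dir, provenance: str | None = None) -> dict:
    """Write counts, sample sheet, annotation and UTR FASTA for an experiment.

    Returns the mapping of logical names to the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = experiment.counts
    paths = {
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
        "utrs": out / "utrs.fasta",
    }
    counts = data.counts.rename_axis("transcript_id").reset_index()
    write_table(counts, paths["counts"], provenance)
    samples = data.samples.rename_axis("library_id").reset_index()
    write_table(samples, paths["samples"], provenance)
    annot = experiment.transcripts[
        ["transcript_id", "mrna_length", "utr3_length", "is_target", "is_spikein"]
    ]
    write_table(annot, paths["annotation"], provenance)
    seqs = experiment.transcripts.loc[~experiment.transcripts["is_spikein"]]
    write_fasta(dict(zip(seqs["transcript_id"], seqs["utr3_seq"])), paths["utrs"])
    return paths


def read_counts(
    counts_path, samples_path, annotation_path=None, spikein_prefixes=("spike", "ERCC-")
) -> FractionCountMatrix:
    """Load a count matrix and its sample sheet into the typed container.

    Spike-in rows are flagged from the annotation table when given,
    otherwise by transcript-id prefix.  Validation (labels, integer
    non-negative counts, sheet coverage) happens in the container and
    raises :class:`~polyafrac.data.DataValidationError` with the offending
    row/column named.
    """
    counts = read_table(counts_path)
    if "transcript_id" not in counts.columns:
        raise DataValidationError("counts TSV must have a 'transcript_id' column")
    counts = counts.set_index("transcript_id")
    samples = read_table(samples_path)
    if "library_id" not in samples.columns:
        raise DataValidationError("sample sheet must have a 'library_id' column")
    samples = samples.set_index("library_id")
    if annotation_path is not None:
        annot = read_annotation(annotation_path)
        spikein = annot["is_spikein"].reindex(counts.index, fill_value=False)
    else:
        spikein = pd.Series(
            [any(str(t).startswith(p) for p in spikein_prefixes) for t in counts.index],
            index=counts.index,
        )
    return FractionCountMatrix(counts, samples, spikein)


def read_annotation(path) -> pd.DataFrame:
    annot = read_table(path)
    if "transcript_id" not in annot.columns:
        raise DataValidationError("annotation TSV must have a 'transcript_id' column")
    for col in ("is_target", "is_spikein"):
        if col in annot.columns:
            annot[col] = annot[col].astype(bool)
    return annot.set_index("transcript_id", drop=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(seqs: dict, path) -> None:
    records = [
        SeqRecord(Seq(s), id=str(name), description="") for name, s in seqs.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# LFQ tables
# ---------------------------------------------------------------------------

def read_lfq(lfq_path, runs_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    table = read_table(lfq_path)
    for col in ("protein_id", "mw_kda"):
        if col not in table.columns:
            raise DataValidationError(f"LFQ table must have a {col!r} column")
    runs = read_table(runs_path)
    if "run_id" not in runs.columns or "arm" not in runs.columns:
        raise DataValidationError("run sheet needs 'run_id' and 'arm' columns")
    return table, runs.set_index("run_id")


def read_contaminants(path) -> set:
    """Plain-text contaminant id list, one id per line, '#' comments allowed."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out
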