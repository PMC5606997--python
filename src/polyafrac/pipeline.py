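"""End-to-end pipeline driver: config validation, staging, reporting."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import io
from .model import PolyadenylationShiftModel
from .simulate import FractionationModel, SimConfig, TailModel, simulate_experiment
from . import downstream
from . import coip as coip_mod

log = logging.getLogger("polyafrac")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Flat, validated configuration for a full pipeline run.

    Either ``simulate`` is true (a synthetic experiment is generated from
    the sim_* parameters) or counts/samples/annotation/UTR paths point at
    existing inputs.  All stage parameters are here so one file reproduces
    a run end to end.
    """

    out_dir: str = "polyafrac_out"
    seed: int = 0
    verbose: bool = False

    # --- input: simulate or load -----------------------------------------
    simulate: bool = True
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    utr_fasta_path: str | None = None

    # --- simulation ------------------------------------------------------
    sim_n_transcripts: int = 2000
    sim_target_fraction: float = 0.1
    sim_replicates: int = 1
    sim_mean_depth: float = 1_000_000.0
    sim_nb_dispersion: float = 0.05
    sim_baseline_mean: float = 75.0
    sim_baseline_shape: float = 2.0
    sim_delta: float = 150.0
    sim_stability_coupling: float = 0.0
    sim_breakpoints: tuple = (30.0, 60.0, 100.0, 150.0, 220.0)
    sim_softness: float = 10.0
    sim_n_spikeins: int = 92
    sim_utr_length_bias: float = 1.0
    sim_planted_motif: str | None = None

    # --- ratio / hit calling ---------------------------------------------
    pseudocount: float = 0.5
    norm_mode: str = "auto"
    q_threshold: float = 0.05
    min_expression: float = 10.0
    long_fractions: tuple = (5, 6)
    reference_fraction: int = 1

    # --- downstream -------------------------------------------------------
    kmer_k: int = 2
    n_perm: int = 1000

    # --- Co-IP (optional stage) -------------------------------------------
    lfq_path: str | None = None
    runs_path: str | None = None
    contaminants_path: str | None = None
    background_floor: float = 1.0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("sim_breakpoints", "long_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def analysis_dict(self) -> dict:
        """Config subset that determines numeric outputs (for provenance
        hashing): excludes output location and verbosity."""
        d = self.as_dict()
        d.pop("out_dir")
        d.pop("verbose")
        return d

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_transcripts=self.sim_n_transcripts,
            target_fraction=self.sim_target_fraction,
            replicates=self.sim_replicates,
            mean_depth=self.sim_mean_depth,
            nb_dispersion=self.sim_nb_dispersion,
            tail_model=TailModel(
                baseline_mean=self.sim_baseline_mean,
                baseline_shape=self.sim_baseline_shape,
                delta=self.sim_delta,
                stability_coupling=self.sim_stability_coupling,
            ),
            fractionation=FractionationModel(
                breakpoints=tuple(self.sim_breakpoints),
                softness=self.sim_softness,
            ),
            n_spikeins=self.sim_n_spikeins,
            utr_length_bias=self.sim_utr_length_bias,
            planted_motif=self.sim_planted_motif,
            seed=self.seed,
        )

    def validate(self) -> None:
        if not self.simulate:
            missing = [
                name
                for name in ("counts_path", "samples_path")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(
                    f"simulate=false requires input paths, missing: {missing}"
                )
        self.sim_config()  # raises on invalid simulation parameters
        if self.q_threshold <= 0 or self.q_threshold >= 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")


def run_all(config: PipelineConfig) -> dict:
    """Execute every applicable stage and write all declared outputs.

    simulate (optional) -> normalize -> ratios (long fractions) -> null fits
    -> hit calls -> downstream analyses -> Co-IP scoring (when LFQ inputs
    given) -> reports.  Returns a bundle of in-memory results; all outputs
    land under ``config.out_dir`` carrying a provenance header line.
    """
    config.validate()
    logging.basicConfig(
        level=logging.DEBUG if config.verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = io.provenance_line(seed=config.seed, config=config.analysis_dict())
    bundle: dict = {"config": config}

    # --- stage: input -----------------------------------------------------
    annotation = None
    utrs = None
    if config.simulate:
        log.info("simulate: n_transcripts=%d target_fraction=%s delta=%s seed=%d",
                 config.sim_n_transcripts, config.sim_target_fraction,
                 config.sim_delta, config.seed)
        experiment = simulate_experiment(config.sim_config())
        io.write_experiment(experiment, out / "simulated", prov)
        data = experiment.counts
        annotation = experiment.transcripts
        utrs = dict(
            zip(
                annotation.loc[~annotation["is_spikein"], "transcript_id"],
                annotation.loc[~annotation["is_spikein"], "utr3_seq"],
            )
        )
        bundle["experiment"] = experiment
    else:
        log.info("load: %s", config.counts_path)
        data = io.read_counts(
            config.counts_path, config.samples_path, config.annotation_path
        )
        if config.annotation_path:
            annotation = io.read_annotation(config.annotation_path)
        if config.utr_fasta_path:
            utrs = io.read_fasta(config.utr_fasta_path)
    bundle["data"] = data

    # --- stage: model fit --------------------------------------------------
    log.info("fit: pseudocount=%s norm=%s q=%s min_expr=%s",
             config.pseudocount, config.norm_mode,
             config.q_threshold, config.min_expression)
    model = PolyadenylationShiftModel(
        data,
        long_fractions=config.long_fractions,
        reference_fraction=config.reference_fraction,
        pseudocount=config.pseudocount,
        normalization=config.norm_mode,
    )
    results = model.fit(
        q_threshold=config.q_threshold, min_expression=config.min_expression
    )
    results.to_dir(out, prov)
    bundle["results"] = results
    log.info("fit: %d combined hits / %d transcripts",
             len(results.hits), len(results.ratio_table))

    # --- stage: downstream -------------------------------------------------
    report: dict = {"n_combined_hits": int(len(results.hits))}
    hits = results.hits
    if annotation is not None and len(hits) and len(hits) < len(results.ratio_table):
        annot_tx = annotation.loc[~annotation["is_spikein"].astype(bool)]
        for feature in ("utr3_length", "mrna_length"):
            res = downstream.length_bias_test(
                hits, annot_tx, feature, n_perm=config.n_perm, seed=config.seed
            )
            report[f"length_bias_{feature}"] = dataclasses.asdict(res)
            log.info("length bias %s: diff=%.1f p=%.4g",
                     feature, res.median_difference, res.p_value)
    if utrs is not None and len(hits):
        expressed = results.ratio_table.index[results.ratio_table["expression_pass"]]
        fg = [utrs[t] for t in hits if t in utrs]
        bg = [utrs[t] for t in expressed if t in utrs]
        if fg and bg:
            enr = downstream.kmer_enrichment(
                fg, bg, k=config.kmer_k, n_perm=config.n_perm, seed=config.seed
            )
            io.write_table(enr, out / "kmer_enrichment.tsv", prov)
            bundle["kmer_enrichment"] = enr
            log.info("kmer enrichment: top %s (log2=%.3f q=%.3g)",
                     enr["kmer"].iloc[0], enr["log2_enrichment"].iloc[0],
                     enr["q"].iloc[0])
    if len(hits) >= 2:
        coupling = downstream.expression_coupling(
            results.ratio_table, results.expression_log2fc()
        )
        report["expression_coupling"] = dataclasses.asdict(coupling)
        log.info("coupling: rho=%.3f p=%.3g (n=%d)",
                 coupling.rho, coupling.p_value, coupling.n_hits)
        bundle["coupling"] = coupling

    # --- stage: Co-IP (optional) -------------------------------------------
    if config.lfq_path and config.runs_path:
        table, runs = io.read_lfq(config.lfq_path, config.runs_path)
        contaminants = (
            io.read_contaminants(config.contaminants_path)
            if config.contaminants_path
            else set()
        )
        scored = coip_mod.score_coip(
            table, runs, config.background_floor, contaminants
        )
        io.write_table(scored, out / "coip_scores.tsv", prov)
        io.write_table(
            coip_mod.export_dotplot(scored), out / "coip_dotplot.tsv", prov
        )
        bundle["coip"] = scored
        log.info("coip: scored %d proteins", len(scored))

    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    (out / "summary.txt").write_text(results.summary() + "\n")
    bundle["report"] = report
    return bundle
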