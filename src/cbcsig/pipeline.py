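"""Orchestration: one reproducible run from simulated cohort to gene signatures.

``run_all`` executes simulate -> startle metrics -> CBC scoring ->
classification -> sequencing selection -> count simulation -> TPM -> DE ->
signature overlap, writing every intermediate table as TSV and a JSON run
manifest (config snapshot, package version, per-file checksums, warnings).
Identical seed and config reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import cbcsig
from cbcsig import expression, scoring, signatures, startle as startle_mod
from cbcsig.physiology import correlate_pairs, physiology_frame
from cbcsig.synthetic import (
    CohortConfig,
    ConfigurationError,
    DePlantSpec,
    PlantedGene,
    simulate_cohort,
    simulate_counts,
    write_cohort,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for an end-to-end demonstration run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    de_spec: DePlantSpec | None = None  # default: demo plant, see default_de_spec()
    de_alpha: float = 0.05
    k_low: int = 3
    k_high: int = 3
    k_control: int = 6
    region: str = "DG"
    direction_consistent: bool = False
    seed: int = 0


def default_de_spec() -> DePlantSpec:
    """A demonstration plant: two resilience-like genes and one susceptibility-like gene.

    Genes shifted in stress_low only separate resilient animals from both
    other groups (the resilience pattern); a gene shifted in stress_high only
    is the susceptibility pattern.
    """
    return DePlantSpec(
        n_genes=300,
        baseline_mean=100.0,
        dispersion=0.05,
        planted=[
            PlantedGene(10, -2.0, ("stress_low",)),
            PlantedGene(20, -2.0, ("stress_low",)),
            PlantedGene(30, 2.0, ("stress_high",)),
        ],
    )


@dataclass
class RunManifest:
    config: dict
    version: str
    outputs: dict[str, str]  # artifact name -> path
    checksums: dict[str, str]  # path -> sha256
    warnings: list[str]
    completed_stages: list[str]
    failed_stage: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_snapshot(config: RunConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        if isinstance(obj, dict):
            return {k: encode(v) for k, v in obj.items()}
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    return encode(config)


def run_all(config: RunConfig, outdir) -> RunManifest:
    """Execute the full pipeline into ``outdir``; always writes a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=_config_snapshot(config),
        version=cbcsig.__version__,
        outputs={},
        checksums={},
        warnings=[],
        completed_stages=[],
    )
    try:
        _run_stages(config, out, manifest)
    except Exception as exc:
        manifest.failed_stage = (
            manifest.failed_stage or f"unknown ({type(exc).__name__}: {exc})"
        )
        _finalize(manifest, out)
        raise
    _finalize(manifest, out)
    return manifest


def _finalize(manifest: RunManifest, out: Path) -> None:
    for path in manifest.outputs.values():
        if Path(path).exists():
            manifest.checksums[path] = _sha256(path)
    manifest.to_json(out / "manifest.json")


def _run_stages(config: RunConfig, out: Path, manifest: RunManifest) -> None:
    # -- simulate ----------------------------------------------------------
    manifest.failed_stage = "simulate"
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = simulate_cohort(cohort_cfg)
    manifest.outputs.update(write_cohort(cohort, out))
    log.info("simulate: %d animals", len(cohort.animals))
    manifest.completed_stages.append("simulate")

    # -- startle summary ---------------------------------------------------
    manifest.failed_stage = "startle"
    results = [
        startle_mod.summarize_trace(animal_id, trace)
        for animal_id, trace in sorted(cohort.traces.items())
    ]
    startle_df = startle_mod.summary_frame(results)
    startle_path = out / "startle_summary.tsv"
    startle_df.to_csv(startle_path, sep="\t", index=False)
    manifest.outputs["startle_summary"] = str(startle_path)
    manifest.completed_stages.append("startle")

    # -- score + classify --------------------------------------------------
    manifest.failed_stage = "score"
    thresholds, scores, labels = scoring.score_cohort(
        cohort.measurements, cohort_cfg.metric_registry
    )
    scoring.thresholds_frame(thresholds).to_csv(
        out / "thresholds.tsv", sep="\t", index=False
    )
    scores_df = scoring.scores_frame(scores, labels)
    scores_df.to_csv(out / "scores.tsv", sep="\t", index=False)
    manifest.outputs["thresholds"] = str(out / "thresholds.tsv")
    manifest.outputs["scores"] = str(out / "scores.tsv")
    manifest.completed_stages.append("score")

    # -- physiology correlations ------------------------------------------
    manifest.failed_stage = "correlate"
    corr = correlate_pairs(
        scores_df,
        physiology_frame(cohort.physiology),
        [("cort_3h", "total"), ("weight_change_pct", "total")],
    )
    corr.to_csv(out / "correlations.tsv", sep="\t", index=False)
    manifest.outputs["correlations"] = str(out / "correlations.tsv")
    manifest.completed_stages.append("correlate")

    # -- select + simulate counts -----------------------------------------
    manifest.failed_stage = "select"
    selection = scoring.select_for_sequencing(
        scores, cohort.groups(), config.k_low, config.k_high, config.k_control
    )
    samples = (
        [(a, "control") for a in selection.control]
        + [(a, "stress_low") for a in selection.stress_low]
        + [(a, "stress_high") for a in selection.stress_high]
    )
    manifest.completed_stages.append("select")

    manifest.failed_stage = "quantify"
    de_spec = config.de_spec or default_de_spec()
    counts = simulate_counts(samples, de_spec, seed=np.random.default_rng(config.seed + 1))
    counts.to_tsv(out / "counts.tsv")
    counts.sample_sheet().to_csv(out / "samples.tsv", sep="\t", index=False)
    manifest.outputs["counts"] = str(out / "counts.tsv")
    manifest.outputs["samples"] = str(out / "samples.tsv")

    tpm = expression.counts_to_tpm(counts)
    log_tpm = expression.log_transform(tpm.values)
    flagged = expression.pca_outlier_flag(log_tpm)
    for i in flagged:
        manifest.warnings.append(f"pca_outlier: sample {counts.sample_ids[i]}")
    manifest.completed_stages.append("quantify")

    # -- DE ----------------------------------------------------------------
    manifest.failed_stage = "de"
    deg_tables = {}
    for contrast in ("C_vs_SL", "C_vs_SH", "SL_vs_SH"):
        res = expression.de_test(counts, contrast, alpha=config.de_alpha)
        sig = res[res["significant"]].drop(columns="significant")
        path = out / f"deg_{contrast}.tsv"
        sig.to_csv(path, sep="\t", index=False)
        manifest.outputs[f"deg_{contrast}"] = str(path)
        deg_tables[contrast] = signatures.DEGTable(
            region=config.region, contrast=contrast, records=sig.reset_index(drop=True)
        )
    manifest.completed_stages.append("de")

    # -- signatures --------------------------------------------------------
    manifest.failed_stage = "signatures"
    sig_sets = signatures.build_signatures(
        deg_tables["SL_vs_SH"],
        deg_tables["C_vs_SL"],
        deg_tables["C_vs_SH"],
        direction_consistent=config.direction_consistent,
    )
    gene_idx = {gid: i for i, gid in enumerate(counts.gene_ids)}
    contrast_groups = ("stress_low", "stress_high")
    mask = np.array([g in contrast_groups for g in counts.sample_groups])
    sub = counts.counts[:, mask].astype(float)
    order = np.argsort(
        [contrast_groups.index(g) for g in np.asarray(counts.sample_groups)[mask]],
        kind="stable",
    )
    n_low = sum(g == "stress_low" for g in counts.sample_groups)
    n_high = int(mask.sum()) - n_low
    phi_common = expression.common_dispersion(
        sub[:, order] / expression.size_factors(sub[:, order]), (n_low, n_high)
    )
    flagged_genes = []
    for key in sorted(sig_sets.resilience | sig_sets.susceptibility):
        values = tpm.values[gene_idx[key.symbol]]
        try:
            if signatures.outlier_driven_filter(
                np.asarray(values)[mask],
                np.asarray(counts.sample_groups)[mask],
                alpha=config.de_alpha,
                dispersion=phi_common,
            ):
                flagged_genes.append(key.symbol)
                manifest.warnings.append(f"outlier_driven: {key.symbol}")
        except signatures.SignatureError:
            pass  # not significant on TPM scale under the single-gene test
    payload = {
        "region": config.region,
        "resilience": sorted(k.symbol for k in sig_sets.resilience),
        "susceptibility": sorted(k.symbol for k in sig_sets.susceptibility),
        "outlier_flagged": sorted(flagged_genes),
        "provenance": {k: list(v) for k, v in sig_sets.provenance.items()},
    }
    sig_path = out / "signatures.json"
    with open(sig_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    manifest.outputs["signatures"] = str(sig_path)
    manifest.completed_stages.append("signatures")
    manifest.failed_stage = None


# ---------------------------------------------------------------------------
# Input validation


@dataclass
class ValidationReport:
    failures: list[str]

    @property
    def ok(self) -> bool:
        return not self.failures


_MEASUREMENT_COLUMNS = {"animal_id", "group", "assay", "metric_name", "value"}
_PHYSIOLOGY_COLUMNS = {"animal_id", "weight_day0", "weight_day1", "cort_30min", "cort_3h"}


def validate_inputs(paths: dict[str, str]) -> ValidationReport:
    """Schema-validate input tables; returns a report, never raises.

    ``paths`` maps table kind (``measurements``, ``physiology``, ``counts``)
    to a TSV path. Unknown kinds are reported as failures.
    """
    failures: list[str] = []
    for kind, path in paths.items():
        try:
            if kind == "measurements":
                df = pd.read_csv(path, sep="\t")
                missing = _MEASUREMENT_COLUMNS - set(df.columns)
                if missing:
                    failures.append(f"{path}: missing column(s) {sorted(missing)}")
                elif not np.issubdtype(df["value"].dtype, np.number):
                    failures.append(f"{path}: column 'value' is not numeric")
            elif kind == "physiology":
                df = pd.read_csv(path, sep="\t")
                missing = _PHYSIOLOGY_COLUMNS - set(df.columns)
                if missing:
                    failures.append(f"{path}: missing column(s) {sorted(missing)}")
            elif kind == "counts":
                df = pd.read_csv(path, sep="\t")
                missing = {"gene_id", "gene_name", "length"} - set(df.columns)
                if missing:
                    failures.append(f"{path}: missing column(s) {sorted(missing)}")
                else:
                    num = df.select_dtypes(include=[np.number]).drop(
                        columns=[c for c in ("length",) if c in df.columns]
                    )
                    if (num < 0).any().any():
                        failures.append(f"{path}: negative count entries")
            else:
                failures.append(f"{path}: unknown table kind {kind!r}")
        except Exception as exc:  # report, never raise
            failures.append(f"{path}: {type(exc).__name__}: {exc}")
    return ValidationReport(failures=failures)
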