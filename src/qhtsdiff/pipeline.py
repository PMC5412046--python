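"""End-to-end orchestration: configuration, IO, and the full analysis run.

A run goes raw screen table (or simulation spec) -> viability normalization
-> 4PL fits -> CRC codes -> per-curve metrics -> differential class calls,
hit sets and target enrichment -> (optionally) expression normalization, DE
and the expression-drug overlay.  All thresholds live in ``PipelineConfig``,
round-trip losslessly through YAML/JSON, and are echoed in the run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crc import CrcRubric, classify_crc
from .differential import (
    class_auc_differential,
    expression_drug_overlay,
    fisher_target_enrichment,
    shared_maxr_hits,
    stringent_potency_hits,
)
from .dose_response import (
    ConcentrationSeries,
    curve_metrics,
    fit_profiles,
    metrics_frame,
    normalize_viability,
)
from .errors import ConfigurationError, DataError
from .expression import (
    collapse_probes,
    hierarchical_cluster,
    housekeeping_normalize,
    linkage_to_newick,
    median_center_probes,
    one_vs_rest_de,
)
from .screen_sim import (
    CELL_LINE_A,
    CELL_LINE_B,
    DESpec,
    ExpressionMatrix,
    LibrarySpec,
    annotations_frame,
    annotations_from_frame,
    generate_expression,
    generate_library,
    generate_screen,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class SeriesConfig:
    n_points: int = 11
    top_molar: float = 46e-6
    dilution: float = 3.0

    def build(self) -> ConcentrationSeries:
        return ConcentrationSeries.default(self.n_points, self.top_molar,
                                           self.dilution)


@dataclass
class DifferentialConfig:
    z_threshold: float = 2.0
    delta_logac50: float = -1.0
    maxr_threshold: float = 30.0
    enrichment_q: float = 0.01
    enrichment_p: float = 0.01
    overlay_fc: float = 2.0


@dataclass
class DEConfig:
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    fdr_threshold: float = 0.1


@dataclass
class SimConfig:
    """Synthetic-screen settings used when ``simulate`` is on."""

    n_compounds: int = 1912
    class_sizes: dict[str, int] | None = None
    fraction_active: float = 0.35
    selective_classes: dict[str, float] = field(
        default_factory=lambda: {"MTOR": -1.5, "TOP2A": -1.5}
    )
    fraction_ambiguous: float = 0.0
    noise_sd: float = 5.0
    n_probes: int = 6000
    n_expression_lines: int = 8
    replicates: int = 3
    de_count: int = 900
    de_log2_effect: float = 1.5
    expression_noise_sd: float = 0.3
    plant_target_de: bool = True


@dataclass
class PipelineConfig:
    simulate: bool = True
    seed: int = 0
    outdir: str = "qhtsdiff_out"
    screen_csv: str | None = None
    annotations_csv: str | None = None
    expression_csv: str | None = None
    cell_line_a: str = CELL_LINE_A
    cell_line_b: str = CELL_LINE_B
    expression_line_of_interest: str | None = None
    series: SeriesConfig = field(default_factory=SeriesConfig)
    rubric: CrcRubric = field(default_factory=CrcRubric)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    de: DEConfig = field(default_factory=DEConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        nested = {
            "series": SeriesConfig,
            "rubric": CrcRubric,
            "differential": DifferentialConfig,
            "de": DEConfig,
            "sim": SimConfig,
        }
        kwargs: dict[str, Any] = {}
        for key, val in d.items():
            if key in nested:
                kwargs[key] = nested[key](**val) if isinstance(val, dict) else val
            else:
                kwargs[key] = val
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigurationError(f"config file {path} is not a mapping")
        return cls.from_dict(payload)

    def apply_override(self, dotted: str, raw: str) -> None:
        """Apply one ``a.b=value`` style override with YAML-typed parsing."""
        target: Any = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            if not hasattr(target, part):
                raise ConfigurationError(f"unknown config key {dotted!r}")
            target = getattr(target, part)
        leaf = parts[-1]
        if not dataclasses.is_dataclass(target) or not hasattr(target, leaf):
            raise ConfigurationError(f"unknown config key {dotted!r}")
        setattr(target, leaf, yaml.safe_load(raw))


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc


# ---------------------------------------------------------------------------
# Expression CSV round-trip (probes x samples with gene/line metadata)
# ---------------------------------------------------------------------------

def write_expression_csv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.insert(0, "gene", [matrix.probe_to_gene.get(p, "") for p in df.index])
    df.insert(1, "is_housekeeping",
              [int(p in matrix.housekeeping_probes) for p in matrix.values.index])
    df.index.name = "probe_id"
    with open(path, "w") as fh:
        fh.write("#line,,," + ",".join(
            matrix.sample_to_line[s] for s in matrix.values.columns) + "\n")
        df.to_csv(fh)


def read_expression_csv(path: str | Path) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#line"):
            raise DataError("expression CSV lacks the '#line' metadata row")
        # header row is probe_id,gene,is_housekeeping,<samples...>; the
        # metadata row mirrors it with "#line" in the first cell
        line_values = first.split(",")[3:]
        df = pd.read_csv(fh, index_col=0)
    sample_cols = [c for c in df.columns if c not in ("gene", "is_housekeeping")]
    if len(line_values) != len(sample_cols):
        raise DataError("'#line' metadata row does not match sample columns")
    return ExpressionMatrix(
        values=df[sample_cols].astype(float),
        sample_to_line=dict(zip(sample_cols, line_values)),
        probe_to_gene={p: g for p, g in df["gene"].items() if isinstance(g, str) and g},
        housekeeping_probes={p for p, v in df["is_housekeeping"].items() if int(v)},
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _line_metrics(records: pd.DataFrame, line: str, series: ConcentrationSeries,
                  rubric: CrcRubric) -> pd.DataFrame:
    sub = records[records["cell_line"] == line]
    if sub.empty:
        raise DataError(f"no screen records for cell line {line!r}")
    profiles = normalize_viability(sub, series)
    fits = fit_profiles(profiles, series)
    metrics = []
    for prof, fit in zip(profiles, fits):
        m = curve_metrics(prof, fit, series)
        m.crc = float(classify_crc(prof, fit, series, rubric))
        metrics.append(m)
    return metrics_frame(metrics)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis and write all result tables.

    Returns a bundle with every intermediate table; files are written only
    after all stages succeed, so failures leave no partial outputs.
    """
    series = config.series.build()
    outdir = Path(config.outdir)
    bundle: dict[str, Any] = {}
    expr_matrix: ExpressionMatrix | None = None

    with _stage("inputs"):
        if config.simulate:
            sim = config.sim
            spec = LibrarySpec(
                n_compounds=sim.n_compounds,
                class_sizes=dict(sim.class_sizes) if sim.class_sizes else None,
                fraction_active=sim.fraction_active,
                selective_classes=dict(sim.selective_classes),
                fraction_ambiguous=sim.fraction_ambiguous,
                seed=config.seed,
            )
            annotations, truth = generate_library(spec, series)
            records = generate_screen(
                annotations, truth, series, noise_sd=sim.noise_sd,
                seed=config.seed + 1,
                cell_lines=(config.cell_line_a, config.cell_line_b),
            )
            forced = (
                {t: 1.5 for t in spec.selective_classes}
                if sim.plant_target_de else {}
            )
            expr_matrix, expr_truth = generate_expression(
                n_probes=sim.n_probes,
                n_lines=sim.n_expression_lines,
                replicates=sim.replicates,
                de_spec=DESpec(count=sim.de_count, log2_effect=sim.de_log2_effect,
                               forced=forced),
                noise_sd=sim.expression_noise_sd,
                seed=config.seed + 2,
                gene_names=sorted({t for a in annotations for t in a.targets}),
            )
            truth.de_genes = expr_truth.de_genes
            bundle["truth"] = truth
        else:
            if not config.screen_csv or not config.annotations_csv:
                raise ConfigurationError(
                    "screen_csv and annotations_csv required when simulate=false"
                )
            records = pd.read_csv(config.screen_csv)
            annotations = annotations_from_frame(pd.read_csv(config.annotations_csv))
            if config.expression_csv:
                expr_matrix = read_expression_csv(config.expression_csv)
        bundle["records"] = records
        bundle["annotations"] = annotations

    with _stage("fit"):
        metrics_a = _line_metrics(records, config.cell_line_a, series, config.rubric)
        metrics_b = _line_metrics(records, config.cell_line_b, series, config.rubric)
        bundle["metrics_a"] = metrics_a
        bundle["metrics_b"] = metrics_b

    top_log = float(series.log10_molar[-1])
    with _stage("differential"):
        diff = class_auc_differential(
            metrics_a, metrics_b, annotations,
            z_threshold=config.differential.z_threshold,
        )
        stringent = stringent_potency_hits(
            metrics_a, metrics_b, top_log,
            delta_threshold=config.differential.delta_logac50,
        )
        shared = shared_maxr_hits(
            metrics_a, metrics_b, threshold_pct=config.differential.maxr_threshold
        )
        bundle["class_differential"] = diff
        bundle["stringent_hits"] = stringent
        bundle["shared_hits"] = shared

    with _stage("enrichment"):
        bundle["enrichment_stringent"] = fisher_target_enrichment(
            stringent, annotations,
            q_threshold=config.differential.enrichment_q,
            p_threshold=config.differential.enrichment_p,
        )
        bundle["enrichment_shared"] = fisher_target_enrichment(
            shared, annotations,
            q_threshold=config.differential.enrichment_q,
            p_threshold=config.differential.enrichment_p,
        )

    if expr_matrix is not None:
        with _stage("expression"):
            norm = housekeeping_normalize(expr_matrix)
            genes = collapse_probes(norm)
            centered = median_center_probes(norm)
            Z, labels = hierarchical_cluster(centered.values, axis="samples")
            line = config.expression_line_of_interest or norm.lines()[0]
            de = one_vs_rest_de(
                genes, norm.sample_to_line, line,
                fc_threshold=config.de.fc_threshold,
                p_threshold=config.de.p_threshold,
                fdr_threshold=config.de.fdr_threshold,
            )
            bundle["expression_matrix"] = norm
            bundle["gene_matrix"] = genes
            bundle["dendrogram_newick"] = linkage_to_newick(Z, labels)
            bundle["de_results"] = de
        with _stage("overlay"):
            bundle["overlay"] = expression_drug_overlay(
                bundle["de_results"], annotations, metrics_a, metrics_b,
                top_log, fc_threshold=config.differential.overlay_fc,
            )

    with _stage("write"):
        outdir.mkdir(parents=True, exist_ok=True)
        records.to_csv(outdir / "screen.csv", index=False)
        annotations_frame(annotations).to_csv(outdir / "annotations.csv", index=False)
        if "truth" in bundle:
            bundle["truth"].to_json(outdir / "truth.json")
        metrics_a.to_csv(outdir / "metrics_line_a.tsv", sep="\t", index=False)
        metrics_b.to_csv(outdir / "metrics_line_b.tsv", sep="\t", index=False)
        diff.to_csv(outdir / "class_differential.tsv", sep="\t", index=False)
        (outdir / "stringent_hits.txt").write_text(
            "\n".join(sorted(stringent)) + ("\n" if stringent else "")
        )
        (outdir / "shared_hits.txt").write_text(
            "\n".join(sorted(shared)) + ("\n" if shared else "")
        )
        bundle["enrichment_stringent"].to_csv(
            outdir / "enrichment_stringent.tsv", sep="\t", index=False
        )
        bundle["enrichment_shared"].to_csv(
            outdir / "enrichment_shared.tsv", sep="\t", index=False
        )
        if expr_matrix is not None:
            write_expression_csv(bundle["expression_matrix"],
                                 outdir / "expression_normalized.csv")
            bundle["de_results"].to_csv(outdir / "de_results.tsv", sep="\t",
                                        index=False)
            (outdir / "sample_dendrogram.nwk").write_text(
                bundle["dendrogram_newick"] + "\n"
            )
            bundle["overlay"].to_csv(outdir / "overlay.tsv", sep="\t", index=False)

        cfg = config.to_dict()
        manifest = {
            "package": "qhtsdiff",
            "version": __version__,
            "seed": config.seed,
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()
            ).hexdigest(),
            "decisions": {
                "auc_from_observed_activity": True,
                "maxr_from_observed_top_dose": True,
                "class_ratio_guard_floor_auc": 1.0,
                "class_zscore_on_log_ratio": True,
                "stringent_delta_logac50_sign": "< -1 (more potent in line A)",
                "censored_logac50_at_top_concentration": True,
                "enrichment_background": "full annotated library",
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        bundle["manifest"] = manifest
    return bundle


def validate_inputs(paths: dict[str, str]) -> list[str]:
    """Schema/report-only check of screen, annotation and expression files.

    Returns a list of human-readable issues; empty means all checks passed.
    """
    issues: list[str] = []
    screen = paths.get("screen_csv")
    ann = paths.get("annotations_csv")
    expr = paths.get("expression_csv")

    ann_ids: set[str] = set()
    if ann:
        try:
            adf = pd.read_csv(ann)
            if "compound_id" not in adf.columns:
                issues.append("annotations: missing 'compound_id' column")
            else:
                dup = adf["compound_id"][adf["compound_id"].duplicated()]
                if len(dup):
                    issues.append(
                        f"annotations: duplicate compound_id ({sorted(set(dup))[:3]})"
                    )
                ann_ids = set(adf["compound_id"].astype(str))
            for col in ("targets", "moa_class"):
                if col not in adf.columns:
                    issues.append(f"annotations: missing {col!r} column")
        except Exception as exc:  # noqa: BLE001
            issues.append(f"annotations: unreadable ({exc})")

    if screen:
        try:
            sdf = pd.read_csv(screen)
            needed = {"compound_id", "cell_line", "conc_index", "raw_signal",
                      "is_control"}
            missing = needed - set(sdf.columns)
            if missing:
                issues.append(f"screen: missing columns {sorted(missing)}")
            else:
                for line, grp in sdf.groupby("cell_line"):
                    n_ctrl = int(grp["is_control"].astype(bool).sum())
                    if n_ctrl == 0:
                        issues.append(f"screen: no vehicle controls for {line!r}")
                    elif n_ctrl < 16:
                        issues.append(
                            f"screen: only {n_ctrl} vehicle controls for {line!r}"
                        )
                wells = sdf[~sdf["is_control"].astype(bool)]
                counts = wells.groupby(["compound_id", "cell_line"])["conc_index"].nunique()
                if len(counts) and counts.nunique() > 1:
                    short = counts[counts < counts.max()]
                    issues.append(
                        f"screen: {len(short)} compound/line pairs with missing doses"
                    )
                if ann_ids:
                    unann = set(wells["compound_id"].astype(str)) - ann_ids
                    if unann:
                        issues.append(
                            f"screen: {len(unann)} unannotated compounds"
                        )
        except Exception as exc:  # noqa: BLE001
            issues.append(f"screen: unreadable ({exc})")

    if expr:
        try:
            read_expression_csv(expr)
        except Exception as exc:  # noqa: BLE001
            issues.append(f"expression: unreadable ({exc})")
    return issues
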