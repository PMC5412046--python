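"""Seeded synthetic qHTS screens and expression matrices with known ground truth.

The generator emulates the structure of a two-cell-line differential viability
screen of an annotated oncology library: ~1900 compounds grouped into
mechanism-of-action (MOA) classes, an 11-point threefold dilution series from
46 uM, 4PL-shaped responses for actives, flat 100%-viability responses for
inactives, vehicle-control (DMSO) wells, and additive Gaussian noise on the
percent-viability scale.  Selected MOA classes can be "planted" as selectively
potent in cell line A (a fixed logAC50 shift applied in line A only), giving
every downstream stage a recoverable truth.

A companion generator produces a triplicate multi-line log2 expression matrix
with planted differentially expressed genes in line 1, a housekeeping probe
set, per-sample brightness offsets, and a many-to-one probe-to-gene map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dose_response import ConcentrationSeries, four_pl
from .errors import ConfigurationError

__all__ = [
    "LibrarySpec",
    "SyntheticTruth",
    "CompoundAnnotation",
    "DESpec",
    "ExpressionMatrix",
    "generate_library",
    "generate_screen",
    "generate_expression",
    "DEFAULT_CLASS_TARGETS",
]

#: Default 20 MOA classes, named by their primary target symbol.
DEFAULT_CLASS_TARGETS: tuple[str, ...] = (
    "MTOR", "TOP2A", "MAP2K1", "BRD4", "PIK3CA", "AKT1", "HDAC1", "EGFR",
    "JAK2", "PTK2", "ROCK1", "PRKCA", "SRC", "ALK", "AURKA", "CDK4",
    "PARP1", "TUBB", "PDE5A", "KIT",
)

CELL_LINE_A = "line_A"
CELL_LINE_B = "line_B"


def _default_class_sizes(n_compounds: int = 1912) -> dict[str, int]:
    base = n_compounds // len(DEFAULT_CLASS_TARGETS)
    rem = n_compounds - base * len(DEFAULT_CLASS_TARGETS)
    sizes = {}
    for i, name in enumerate(DEFAULT_CLASS_TARGETS):
        sizes[name] = base + (1 if i < rem else 0)
    return sizes


@dataclass
class LibrarySpec:
    """Composition of the synthetic compound library.

    ``selective_classes`` maps MOA-class name to a potency shift in log10
    units applied to line A only (negative = more potent in line A).
    """

    n_compounds: int = 1912
    class_sizes: dict[str, int] | None = None
    fraction_active: float = 0.35
    selective_classes: dict[str, float] = field(
        default_factory=lambda: {"MTOR": -1.5, "TOP2A": -1.5}
    )
    fraction_ambiguous: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_sizes is None:
            self.class_sizes = _default_class_sizes(self.n_compounds)

    def validate(self) -> None:
        if sum(self.class_sizes.values()) > self.n_compounds:
            raise ConfigurationError("sum of class_sizes exceeds n_compounds")
        if not 0.0 <= self.fraction_active <= 1.0:
            raise ConfigurationError("fraction_active must be in [0, 1]")
        if not 0.0 <= self.fraction_ambiguous <= 1.0:
            raise ConfigurationError("fraction_ambiguous must be in [0, 1]")
        missing = set(self.selective_classes) - set(self.class_sizes)
        if missing:
            raise ConfigurationError(
                f"selective classes not in class_sizes: {sorted(missing)}"
            )


@dataclass
class CompoundAnnotation:
    """Compound-to-target/mechanism map defining drug classes and the
    enrichment background."""

    compound_id: str
    name: str
    targets: frozenset[str]
    moa_class: str
    stage: str = ""


@dataclass
class SyntheticTruth:
    """Planted ground truth for a generated screen and expression matrix."""

    active_compounds: dict[str, set[str]] = field(default_factory=dict)
    planted_selective_classes: set[str] = field(default_factory=set)
    #: (compound_id, cell_line) -> {"top", "bottom", "logac50", "hill"}
    true_curve_params: dict[tuple[str, str], dict[str, float]] = field(
        default_factory=dict
    )
    #: gene -> planted signed log2 fold change (line 1 vs rest)
    de_genes: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "active_compounds": {k: sorted(v) for k, v in self.active_compounds.items()},
            "planted_selective_classes": sorted(self.planted_selective_classes),
            "true_curve_params": [
                {"compound_id": c, "cell_line": l, **params}
                for (c, l), params in self.true_curve_params.items()
            ],
            "de_genes": self.de_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        truth = cls(
            active_compounds={
                k: set(v) for k, v in payload["active_compounds"].items()
            },
            planted_selective_classes=set(payload["planted_selective_classes"]),
            de_genes=dict(payload.get("de_genes", {})),
        )
        for rec in payload["true_curve_params"]:
            key = (rec["compound_id"], rec["cell_line"])
            truth.true_curve_params[key] = {
                k: rec[k] for k in ("top", "bottom", "logac50", "hill")
            }
        return truth


def generate_library(
    spec: LibrarySpec,
    series: ConcentrationSeries | None = None,
) -> tuple[list[CompoundAnnotation], SyntheticTruth]:
    """Draw a seeded compound library with planted per-class selectivity.

    Actives get a complete-curve parameter draw: hill ~ U[0.8, 2.5], true
    logAC50 uniform over the span of the central 7 points of the series (so
    curves are mostly complete), bottom ~ U[0, 60] (efficacy 40-100%),
    top = 100.  Compounds in a selective class that are active receive the
    class's logAC50 shift in line A, applied exactly.  An optional
    ``fraction_ambiguous`` of actives is pushed to the top edge of the range
    to produce incomplete/single-dose curves for rubric edge-case testing.
    """
    spec.validate()
    series = series or ConcentrationSeries.default()
    x = series.log10_molar
    if len(x) < 9:
        raise ConfigurationError("series too short for the central-7-point draw")
    lo, hi = x[2], x[-3]  # central 7 points of an 11-point series
    rng = np.random.default_rng(spec.seed)

    class_of: list[str] = []
    for name, size in spec.class_sizes.items():
        class_of.extend([name] * size)
    class_of.extend(["other"] * (spec.n_compounds - len(class_of)))

    width = len(str(spec.n_compounds))
    annotations: list[CompoundAnnotation] = []
    truth = SyntheticTruth(
        active_compounds={CELL_LINE_A: set(), CELL_LINE_B: set()},
        planted_selective_classes=set(spec.selective_classes),
    )
    all_targets = sorted(set(spec.class_sizes))
    for i, moa in enumerate(class_of):
        cid = f"CPD-{i + 1:0{width}d}"
        targets = {moa}
        # a minority of compounds are annotated against a second target
        if rng.random() < 0.10 and len(all_targets) > 1:
            extra = all_targets[int(rng.integers(len(all_targets)))]
            targets.add(extra)
        annotations.append(
            CompoundAnnotation(
                compound_id=cid,
                name=f"cmpd_{moa.lower()}_{i + 1}",
                targets=frozenset(targets),
                moa_class=moa,
                stage="preclinical",
            )
        )
        active = rng.random() < spec.fraction_active
        if not active:
            continue
        hill = float(rng.uniform(0.8, 2.5))
        logac50 = float(rng.uniform(lo, hi))
        bottom = float(rng.uniform(0.0, 60.0))
        if spec.fraction_ambiguous > 0 and rng.random() < spec.fraction_ambiguous:
            # incomplete responder: AC50 at/beyond the top tested dose
            logac50 = float(rng.uniform(x[-2], x[-1] + 0.5 * series.log_step))
        base = {"top": 100.0, "bottom": bottom, "logac50": logac50, "hill": hill}
        shifted = dict(base)
        if moa in spec.selective_classes:
            shifted["logac50"] = logac50 + spec.selective_classes[moa]
        truth.true_curve_params[(cid, CELL_LINE_A)] = shifted
        truth.true_curve_params[(cid, CELL_LINE_B)] = base
        truth.active_compounds[CELL_LINE_A].add(cid)
        truth.active_compounds[CELL_LINE_B].add(cid)
    return annotations, truth


def generate_screen(
    annotations: Sequence[CompoundAnnotation],
    truth: SyntheticTruth,
    series: ConcentrationSeries | None = None,
    noise_sd: float = 5.0,
    seed: int = 0,
    control_scale: float = 1000.0,
    n_controls_per_line: int = 32,
    cell_lines: Sequence[str] = (CELL_LINE_A, CELL_LINE_B),
) -> pd.DataFrame:
    """Generate the long-format raw screen table for both cell lines.

    Percent viability (4PL for actives, flat 100 for inactives) gets additive
    Gaussian noise of sd ``noise_sd`` on the viability scale and is then
    mapped onto a luminescence-like raw signal around ``control_scale``.
    Vehicle-control wells are drawn around 100% with the same noise model.
    Raw signals are floored at a small positive value (luminescence cannot
    be negative).
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if n_controls_per_line < 16:
        raise ConfigurationError("need >=16 vehicle-control wells per cell line")
    series = series or ConcentrationSeries.default()
    x = series.log10_molar
    conc = np.asarray(series.concentrations_molar)
    rng = np.random.default_rng(seed)

    for line in cell_lines:
        for cid in truth.active_compounds.get(line, set()):
            if (cid, line) not in truth.true_curve_params:
                raise ConfigurationError(
                    f"active compound {cid} lacks curve parameters for {line}"
                )

    frames = []
    n = len(series)
    for line in cell_lines:
        active = truth.active_compounds.get(line, set())
        for ann in annotations:
            params = truth.true_curve_params.get((ann.compound_id, line))
            if ann.compound_id in active and params is not None:
                viab = four_pl(x, params["top"], params["bottom"],
                               params["logac50"], params["hill"])
            else:
                viab = np.full(n, 100.0)
            if noise_sd > 0:
                viab = viab + rng.normal(0.0, noise_sd, n)
            raw = np.maximum(viab / 100.0 * control_scale, 1e-3 * control_scale)
            frames.append(
                pd.DataFrame(
                    {
                        "compound_id": ann.compound_id,
                        "cell_line": line,
                        "conc_index": np.arange(n),
                        "conc_molar": conc,
                        "raw_signal": raw,
                        "is_control": False,
                    }
                )
            )
        ctrl = np.full(n_controls_per_line, 100.0)
        if noise_sd > 0:
            ctrl = ctrl + rng.normal(0.0, noise_sd, n_controls_per_line)
        frames.append(
            pd.DataFrame(
                {
                    "compound_id": "DMSO",
                    "cell_line": line,
                    "conc_index": -1,
                    "conc_molar": 0.0,
                    "raw_signal": np.maximum(
                        ctrl / 100.0 * control_scale, 1e-3 * control_scale
                    ),
                    "is_control": True,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def annotations_frame(annotations: Sequence[CompoundAnnotation]) -> pd.DataFrame:
    """Annotation table (CSV-ready): targets joined with ';'."""
    return pd.DataFrame(
        {
            "compound_id": [a.compound_id for a in annotations],
            "name": [a.name for a in annotations],
            "targets": [";".join(sorted(a.targets)) for a in annotations],
            "moa_class": [a.moa_class for a in annotations],
            "stage": [a.stage for a in annotations],
        }
    )


def annotations_from_frame(df: pd.DataFrame) -> list[CompoundAnnotation]:
    out = []
    for rec in df.itertuples(index=False):
        targets = frozenset(t for t in str(rec.targets).split(";") if t)
        out.append(
            CompoundAnnotation(
                compound_id=str(rec.compound_id),
                name=str(getattr(rec, "name", "")),
                targets=targets,
                moa_class=str(rec.moa_class),
                stage=str(getattr(rec, "stage", "")),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Expression generator
# ---------------------------------------------------------------------------

@dataclass
class DESpec:
    """Planted differential-expression signal: ``count`` genes at
    +/- ``log2_effect`` in line 1 vs rest; ``forced`` pins named genes to a
    given signed effect (used to align planted DE genes with drug targets)."""

    count: int = 900
    log2_effect: float = 1.5
    forced: dict[str, float] = field(default_factory=dict)


@dataclass
class ExpressionMatrix:
    """Probe-level log2 intensities plus the maps needed downstream."""

    values: pd.DataFrame  # probes x samples
    sample_to_line: dict[str, str]
    probe_to_gene: dict[str, str]
    housekeeping_probes: set[str]

    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.values.columns:
            seen.setdefault(self.sample_to_line[s], None)
        return list(seen)


def generate_expression(
    n_probes: int = 6000,
    n_lines: int = 8,
    replicates: int = 3,
    de_spec: DESpec | None = None,
    noise_sd: float = 0.3,
    seed: int = 0,
    gene_names: Sequence[str] = (),
    n_housekeeping: int = 20,
    multi_probe_fraction: float = 0.1,
    sample_scale_sd: float = 0.5,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a triplicate multi-line log2 expression matrix.

    Model per probe p (gene g) and sample s of line l:

    ``y[p, s] = baseline[g] + effect[g] * [l == line 1] + scale[s] + noise``

    with gene baselines ~ N(8, 1.5), per-sample brightness offsets
    ~ N(0, sample_scale_sd) (removed by housekeeping normalization), and
    replicate noise ~ N(0, noise_sd).  A ``multi_probe_fraction`` of genes is
    covered by two probes; the designated housekeeping probes carry no
    planted effect.  ``gene_names`` seeds the first gene symbols so planted
    DE genes can coincide with annotated drug targets.
    """
    de_spec = de_spec or DESpec()
    if noise_sd < 0 or sample_scale_sd < 0:
        raise ConfigurationError("noise sds must be >= 0")
    if de_spec.count > n_probes:
        raise ConfigurationError("de count exceeds n_probes")
    if replicates < 2:
        raise ConfigurationError("need >=2 replicates per line")
    rng = np.random.default_rng(seed)

    # gene roster: named genes first, then synthetic symbols; housekeeping last
    n_multi = int(round(n_probes * multi_probe_fraction / (1 + multi_probe_fraction)))
    n_genes = n_probes - n_multi - n_housekeeping
    genes = list(gene_names)[:n_genes]
    genes += [f"GENE{i + 1:05d}" for i in range(len(genes), n_genes)]
    hk_genes = [f"HK{i + 1:02d}" for i in range(n_housekeeping)]

    probe_to_gene: dict[str, str] = {}
    probe_genes: list[str] = []
    multi = list(rng.choice(n_genes, size=n_multi, replace=False)) if n_multi else []
    k = 0
    for gi, g in enumerate(genes):
        k += 1
        probe_to_gene[f"ILMN_{k:06d}"] = g
        probe_genes.append(g)
    for gi in multi:
        k += 1
        probe_to_gene[f"ILMN_{k:06d}"] = genes[int(gi)]
        probe_genes.append(genes[int(gi)])
    hk_probes = []
    for g in hk_genes:
        k += 1
        pid = f"ILMN_{k:06d}"
        probe_to_gene[pid] = g
        probe_genes.append(g)
        hk_probes.append(pid)
    probes = list(probe_to_gene)

    # planted effects per gene (housekeeping excluded)
    effects: dict[str, float] = {}
    for g, eff in de_spec.forced.items():
        if g not in set(genes):
            raise ConfigurationError(f"forced DE gene {g!r} not in gene roster")
        effects[g] = float(eff)
    candidates = [g for g in genes if g not in effects]
    n_draw = de_spec.count - len(de_spec.forced)
    if n_draw < 0:
        n_draw = 0
    if n_draw > len(candidates):
        raise ConfigurationError("de count exceeds available genes")
    chosen = rng.choice(len(candidates), size=n_draw, replace=False) if n_draw else []
    for gi in chosen:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        effects[candidates[int(gi)]] = sign * de_spec.log2_effect

    lines = [f"GC-{i + 1:02d}" for i in range(n_lines)]
    samples: list[str] = []
    sample_to_line: dict[str, str] = {}
    for l in lines:
        for r in range(replicates):
            s = f"{l}_r{r + 1}"
            samples.append(s)
            sample_to_line[s] = l

    baseline = rng.normal(8.0, 1.5, len(genes) + len(hk_genes))
    base_of = {g: baseline[i] for i, g in enumerate(genes + hk_genes)}
    scale = rng.normal(0.0, sample_scale_sd, len(samples)) if sample_scale_sd > 0 else (
        np.zeros(len(samples))
    )

    gene_base = np.array([base_of[g] for g in probe_genes])
    gene_eff = np.array([effects.get(g, 0.0) for g in probe_genes])
    is_line1 = np.array([sample_to_line[s] == lines[0] for s in samples])
    vals = gene_base[:, None] + gene_eff[:, None] * is_line1[None, :] + scale[None, :]
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, vals.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(vals, index=probes, columns=samples),
        sample_to_line=sample_to_line,
        probe_to_gene=probe_to_gene,
        housekeeping_probes=set(hk_probes),
    )
    truth = SyntheticTruth(de_genes=effects)
    return matrix, truth
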