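"""End-to-end orchestration: dataset -> metrics -> statistics -> report.

``run_analysis`` reproduces the analysis surface of a mixed-vs-monoculture
nutrient-cycling study as machine-readable tables:

(a) within-species across-stand comparisons (Tukey HSD when a species grows
    in three stands, Student's t when in two) and across-species
    within-stand comparisons, each with compact letters;
(b) two-way factorial ANOVA (stand class x species) per response on the
    complete species-pair layouts;
(c) mixture-effect percentage changes of every concentration and
    resorption efficiency relative to the monoculture;
(d) Pearson correlation matrices of leaf, structure and soil variables per
    species and pooled;
(e) random-forest %IncMSE importance per response, per species and pooled;
(f) linear-regression panels linking resorption efficiencies to leaf
    concentrations.

Letter-case convention: lowercase letters compare the same species across
stand types, uppercase letters compare species within one stand. Error bars
in the means table are standard errors at the chosen replicate unit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .dataset import Dataset, load_dataset
from .exceptions import DomainError, StandmixError
from .metrics import MLCF_ANGIOSPERM, add_trait_columns, delta_percent, resorption_table
from .stats import (
    gate_and_transform,
    linear_fit,
    one_way_anova,
    pearson_matrix,
    rf_importance,
    stars,
    student_t,
    tukey_hsd,
    two_way_anova,
    zscore,
)
from .synthetic import MONO_STAND, default_design, generate_study

#: responses compared across stands/species
RESPONSES = ("GLNC", "GLPC", "SLNC", "SLPC", "NRE", "PRE", "RRE")
#: predictor set for correlations and forests: structure, leaf morphology, soil
PREDICTORS = (
    "AH", "DBH", "CA", "SLA", "LDMC", "LD",
    "pH", "BD", "SA", "SI", "CL", "SOC", "TN", "TP", "AN", "AP",
)
RF_RESPONSES = ("GLNC", "GLPC", "SLNC", "SLPC", "NRE", "PRE")
REGRESSION_PANELS = (
    ("NRE", "PRE"),
    ("NRE", "GLNC"),
    ("PRE", "GLPC"),
    ("NRE", "SLNC"),
    ("PRE", "SLPC"),
)

_RENAME = {
    "GLNC_gkg": "GLNC",
    "GLPC_gkg": "GLPC",
    "SLNC_gkg": "SLNC",
    "SLPC_gkg": "SLPC",
    "AH_m": "AH",
    "DBH_cm": "DBH",
    "CA_m2": "CA",
    "BD_gcm3": "BD",
    "SA_pct": "SA",
    "SI_pct": "SI",
    "CL_pct": "CL",
    "SOC_gkg": "SOC",
    "TN_gkg": "TN",
    "TP_gkg": "TP",
    "AN_mgkg": "AN",
    "AP_mgkg": "AP",
}


@dataclass
class RunConfig:
    """Serializable configuration of one analysis run."""

    input_dir: str | None = None  # load a dataset; None -> simulate the default design
    seed: int = 0
    mlcf: float = MLCF_ANGIOSPERM
    level: str = "tree"  # NuRE aggregation: per-tree then average, or ratio of means
    replicate_unit: str = "tree"  # "tree" or "plot": unit entering the tests
    alpha: float = 0.05
    rf_trees: int = 500
    rf_mtry: int | None = None
    rf_min_leaf: int = 5
    gate: bool = True  # Shapiro-Wilk/Levene gating with log fallback

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(**{k: v for k, v in payload.items() if k in cls.__dataclass_fields__})


@dataclass
class ReportBundle:
    means: pd.DataFrame
    letters: pd.DataFrame
    anova: pd.DataFrame
    ttests: pd.DataFrame
    deltas: pd.DataFrame
    correlations: pd.DataFrame
    regressions: pd.DataFrame
    importance: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)

    _FILES = {
        "means": "metrics.csv",
        "letters": "tukey.csv",
        "anova": "anova.csv",
        "ttests": "ttests.csv",
        "deltas": "deltas.csv",
        "correlations": "correlations.csv",
        "regressions": "regressions.csv",
        "importance": "importance.csv",
    }

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        checksums = {}
        for attr, fname in self._FILES.items():
            path = outdir / fname
            getattr(self, attr).to_csv(path, index=False)
            checksums[fname] = hashlib.sha256(path.read_bytes()).hexdigest()
        prov = dict(self.provenance)
        prov["checksums"] = checksums
        prov["errors"] = self.errors
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(prov, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return outdir


def analysis_table(dataset: Dataset, mlcf: float = MLCF_ANGIOSPERM) -> pd.DataFrame:
    """Per-tree table with derived traits, NuRE and joined plot soil."""
    trees = add_trait_columns(dataset.trees)
    res = resorption_table(dataset, level="tree", mlcf=mlcf)
    trees = trees.merge(res[["tree_id", "NRE", "PRE", "RRE", "limitation"]], on="tree_id")
    soil = dataset.soil.drop(columns=["stand_type"])
    trees = trees.merge(soil, on="plot_id", how="left")
    return trees.rename(columns=_RENAME)


def _replicates(table: pd.DataFrame, unit: str) -> pd.DataFrame:
    """Collapse the per-tree table to the replicate unit entering the tests."""
    if unit == "tree":
        return table
    if unit == "plot":
        keys = ["species", "stand_type", "plot_id"]
        numeric = table.select_dtypes("number").columns
        return table.groupby(keys, as_index=False)[list(numeric)].mean()
    raise ValueError(f"replicate_unit must be 'tree' or 'plot', got {unit!r}")


def _gated(groups, gate: bool, alpha: float):
    """Apply the assumption gate, falling back to raw data when log is impossible."""
    if not gate:
        return groups, "none"
    try:
        out, report = gate_and_transform(groups, alpha=alpha)
        return out, report.transform
    except DomainError:
        warnings.warn("log transform impossible (non-positive values); using raw data")
        return groups, "none"


def _stands_of(table: pd.DataFrame, species: str) -> list[str]:
    return sorted(table.loc[table["species"] == species, "stand_type"].unique())


def run_analysis(config: RunConfig, dataset: Dataset | None = None) -> ReportBundle:
    """Execute the full analysis; stage failures are collected, not fatal."""
    if dataset is None:
        if config.input_dir is not None:
            dataset = load_dataset(config.input_dir)
        else:
            dataset, _ = generate_study(default_design(), seed=config.seed)

    table = analysis_table(dataset, mlcf=config.mlcf)
    reps = _replicates(table, config.replicate_unit)
    alpha = config.alpha
    species_list = sorted(table["species"].unique())
    stand_list = sorted(table["stand_type"].unique())

    errors: list[str] = []
    means_rows, letter_rows, anova_frames, ttest_rows = [], [], [], []

    # --- cell summaries ---------------------------------------------------
    for response in RESPONSES:
        for (sp, stand), cell in reps.groupby(["species", "stand_type"]):
            vals = cell[response].to_numpy()
            means_rows.append(
                {
                    "species": sp,
                    "stand_type": stand,
                    "variable": response,
                    "level": config.replicate_unit,
                    "mean": vals.mean(),
                    "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                }
            )

    # --- (a) within-species across stands (lowercase letters) -------------
    for response in RESPONSES:
        for sp in species_list:
            stands = _stands_of(reps, sp)
            groups = [
                reps.loc[
                    (reps["species"] == sp) & (reps["stand_type"] == s), response
                ].to_numpy()
                for s in stands
            ]
            raw_means = [g.mean() for g in groups]
            try:
                gated, transform = _gated(groups, config.gate, alpha)
                if len(stands) >= 3:
                    aov = one_way_anova(gated, alpha=alpha)
                    frame = pd.DataFrame(
                        {
                            "layout": f"within-species:{sp}",
                            "response": response,
                            "term": ["stand_type", "Residual"],
                            "df": [aov.df[0], aov.df[1]],
                            "sum_sq": [
                                aov.effect["ss_between"],
                                aov.effect["ss_within"],
                            ],
                            "F": [aov.statistic, np.nan],
                            "p": [aov.pvalue, np.nan],
                        }
                    )
                    anova_frames.append(frame)
                    _, letters = tukey_hsd(gated, labels=stands, alpha=alpha)
                elif len(stands) == 2:
                    t = student_t(gated[0], gated[1], alpha=alpha)
                    ttest_rows.append(
                        {
                            "scope": "within-species",
                            "key": sp,
                            "response": response,
                            "group_a": stands[0],
                            "group_b": stands[1],
                            "t": t.statistic,
                            "df": t.df[0],
                            "p": t.pvalue,
                            "transform": transform,
                        }
                    )
                    if t.pvalue < alpha:
                        hi, lo = (
                            (stands[0], stands[1])
                            if raw_means[0] >= raw_means[1]
                            else (stands[1], stands[0])
                        )
                        letters = {hi: "a", lo: "b"}
                    else:
                        letters = {s: "a" for s in stands}
                else:
                    letters = {stands[0]: "a"}
                    transform = "none"
                for s, mean in zip(stands, raw_means):
                    letter_rows.append(
                        {
                            "scope": "within-species",
                            "key": sp,
                            "response": response,
                            "group": s,
                            "mean": mean,
                            "letter": letters[s],
                            "transform": transform,
                        }
                    )
            except StandmixError as exc:
                errors.append(f"within-species {sp}/{response}: {exc}")

    # --- (b) across species within stand (uppercase letters) --------------
    for response in RESPONSES:
        for stand in stand_list:
            sub = reps[reps["stand_type"] == stand]
            sps_here = sorted(sub["species"].unique())
            groups = [
                sub.loc[sub["species"] == sp, response].to_numpy() for sp in sps_here
            ]
            raw_means = [g.mean() for g in groups]
            try:
                if len(sps_here) == 1:
                    letters = {sps_here[0]: "A"}
                    transform = "none"
                else:
                    gated, transform = _gated(groups, config.gate, alpha)
                    t = student_t(gated[0], gated[1], alpha=alpha)
                    ttest_rows.append(
                        {
                            "scope": "within-stand",
                            "key": stand,
                            "response": response,
                            "group_a": sps_here[0],
                            "group_b": sps_here[1],
                            "t": t.statistic,
                            "df": t.df[0],
                            "p": t.pvalue,
                            "transform": transform,
                        }
                    )
                    if t.pvalue < alpha:
                        hi, lo = (
                            (sps_here[0], sps_here[1])
                            if raw_means[0] >= raw_means[1]
                            else (sps_here[1], sps_here[0])
                        )
                        letters = {hi: "A", lo: "B"}
                    else:
                        letters = {sp: "A" for sp in sps_here}
                for sp, mean in zip(sps_here, raw_means):
                    letter_rows.append(
                        {
                            "scope": "within-stand",
                            "key": stand,
                            "response": response,
                            "group": sp,
                            "mean": mean,
                            "letter": letters[sp],
                            "transform": transform,
                        }
                    )
            except StandmixError as exc:
                errors.append(f"within-stand {stand}/{response}: {exc}")

    # --- (c) two-way factorial on complete species-pair layouts -----------
    for mixture in ("RPAD", "RPAS"):
        if mixture not in stand_list:
            continue
        layout = pair_layout(reps, mixture)
        for response in RESPONSES:
            try:
                frame = two_way_anova(
                    layout[response],
                    layout["stand_class"],
                    layout["species"],
                    a_name="stand_type",
                    b_name="species",
                    alpha=alpha,
                )
                frame.insert(0, "response", response)
                frame.insert(0, "layout", f"pair:{mixture}")
                anova_frames.append(frame)
            except StandmixError as exc:
                errors.append(f"two-way {mixture}/{response}: {exc}")

    # --- (d) mixture-effect deltas ----------------------------------------
    delta_rows = []
    cell_means = reps.groupby(["species", "stand_type"])[list(RESPONSES)].mean()
    for sp in species_list:
        mono = MONO_STAND.get(sp)
        if mono is None or (sp, mono) not in cell_means.index:
            continue
        for stand in _stands_of(reps, sp):
            if stand == mono:
                continue
            for quantity in ("GLNC", "GLPC", "SLNC", "SLPC", "NRE", "PRE", "RRE"):
                try:
                    d = delta_percent(
                        cell_means.loc[(sp, stand), quantity],
                        cell_means.loc[(sp, mono), quantity],
                    )
                except StandmixError as exc:
                    errors.append(f"delta {sp}/{stand}/{quantity}: {exc}")
                    continue
                delta_rows.append(
                    {
                        "species": sp,
                        "mixed_stand": stand,
                        "mono_stand": mono,
                        "quantity": quantity,
                        "delta_pct": d,
                    }
                )

    # --- (e) correlations, (f) forests, (g) regressions --------------------
    corr_rows, imp_rows, reg_rows = [], [], []
    subsets = [(sp, table[table["species"] == sp]) for sp in species_list]
    subsets.append(("all", table))
    variables = [v for v in RESPONSES if v != "RRE"] + list(PREDICTORS)
    for name, sub in subsets:
        try:
            corr = pearson_matrix(sub[variables])
            long = corr.to_long()
            long.insert(0, "subset", name)
            corr_rows.append(long)
        except StandmixError as exc:
            errors.append(f"correlations {name}: {exc}")
        for response in RF_RESPONSES:
            try:
                frame = sub[list(PREDICTORS) + [response]].dropna()
                std = zscore(frame)
                imp = rf_importance(
                    std[list(PREDICTORS)],
                    std[response],
                    n_trees=config.rf_trees,
                    mtry=config.rf_mtry,
                    min_samples_leaf=config.rf_min_leaf,
                    seed=config.seed,
                )
                imp.insert(0, "target", response)
                imp.insert(0, "subset", name)
                imp_rows.append(imp)
            except StandmixError as exc:
                errors.append(f"importance {name}/{response}: {exc}")
        for response, predictor in REGRESSION_PANELS:
            try:
                fit = linear_fit(sub[predictor], sub[response], alpha=alpha)
                reg_rows.append(
                    {
                        "subset": name,
                        "response": response,
                        "predictor": predictor,
                        "slope": fit.effect["slope"],
                        "intercept": fit.effect["intercept"],
                        "r_squared": fit.effect["r_squared"],
                        "t": fit.statistic,
                        "df": fit.df[0],
                        "p": fit.pvalue,
                        "stars": stars(fit.pvalue),
                        "n": len(sub),
                    }
                )
            except StandmixError as exc:
                errors.append(f"regression {name}/{response}~{predictor}: {exc}")

    provenance = {
        "seed": config.seed,
        "config": config.to_dict(),
        "standmix_version": __version__,
        "dataset_provenance": dataset.provenance,
    }
    return ReportBundle(
        means=pd.DataFrame(means_rows),
        letters=pd.DataFrame(letter_rows),
        anova=(
            pd.concat(anova_frames, ignore_index=True)
            if anova_frames
            else pd.DataFrame(columns=["layout", "response", "term", "df", "sum_sq", "F", "p"])
        ),
        ttests=pd.DataFrame(ttest_rows),
        deltas=pd.DataFrame(delta_rows),
        correlations=(
            pd.concat(corr_rows, ignore_index=True) if corr_rows else pd.DataFrame()
        ),
        regressions=pd.DataFrame(reg_rows),
        importance=(
            pd.concat(imp_rows, ignore_index=True) if imp_rows else pd.DataFrame()
        ),
        provenance=provenance,
        errors=errors,
    )


def pair_layout(table: pd.DataFrame, mixture: str) -> pd.DataFrame:
    """Complete 2x2 layout for one mixture: (mono, mixed) x its two species.

    The full field design is incomplete (no species grows in every stand),
    so factorial questions are asked on the species-pair layouts: each
    species' monoculture trees labelled stand_class="mono" and its trees in
    the mixture labelled stand_class="mixed".
    """
    # mixture labels concatenate two 2-letter species codes, e.g. RPAD -> RP, AD
    species_pair = [mixture[:2], mixture[2:]]
    parts = []
    for sp in species_pair:
        mono = table[(table["species"] == sp) & (table["stand_type"] == MONO_STAND[sp])]
        mixed = table[(table["species"] == sp) & (table["stand_type"] == mixture)]
        mono = mono.assign(stand_class="mono")
        mixed = mixed.assign(stand_class="mixed")
        parts.extend([mono, mixed])
    return pd.concat(parts, ignore_index=True)
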