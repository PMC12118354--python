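"""Seeded synthetic study generator with known ground truth.

The generator emulates a temperate-plantation sampling design from the Loess
Hilly Region: five stand types — monocultures of *Robinia pseudoacacia* (RP,
an N2-fixing legume), *Amygdalus davidiana* (AD) and *Armeniaca sibirica*
(AS), and the two-species mixtures RPAD and RPAS — with three 20 m x 20 m
plots per stand type (15 plots) and five trees per species per plot. Each
tree carries structure (AH, DBH, CA), raw leaf morphology (FW, DW, LT, LA)
and green/senescent leaf N and P concentrations; each plot carries topsoil
physicochemistry.

Ground truth. Every species x stand cell has true mean green concentrations
(GLNC, GLPC) and true resorption efficiencies (NRE, PRE). Senescent
concentrations are *derived* by inverting the mass-loss-corrected resorption
formula,

    SLNC_true = GLNC_true x (1 - NRE/100) / MLCF,

so that with noise switched off the computed per-tree NuRE recovers the
configured truth exactly. Default mixture effect sizes are calibrated
percentage changes of the true cell means (mixed vs. monoculture); the
monoculture anchors are field-realistic synthetic stand-ins, since the
underlying field data are not public.

Noise model: concentrations are multiplicative lognormal around the cell
mean (mean-exact parameterisation, strictly positive); structure, morphology
and soil covariates are zero-truncated normal; soil texture is a Dirichlet
composition scaled to 100. One RNG stream per plot and per tree, keyed
deterministically from the dataset seed, so enlarging the design never
perturbs earlier draws.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._version import __version__
from .dataset import Dataset, SOIL_COLUMNS, TREE_COLUMNS
from .exceptions import DesignError
from .metrics import MLCF_ANGIOSPERM, classify_limitation, delta_percent

SPECIES = ("RP", "AD", "AS")
SPECIES_NAMES = {
    "RP": "Robinia pseudoacacia",
    "AD": "Amygdalus davidiana",
    "AS": "Armeniaca sibirica",
}

#: stand type -> species composition (monocultures one species, mixtures two)
DEFAULT_STAND_COMPOSITION = {
    "RP": ("RP",),
    "AD": ("AD",),
    "AS": ("AS",),
    "RPAD": ("RP", "AD"),
    "RPAS": ("RP", "AS"),
}

#: species -> its monoculture stand label
MONO_STAND = {"RP": "RP", "AD": "AD", "AS": "AS"}

#: Calibrated mixture effects: percent change of the *true* cell mean in the
#: mixture relative to the species' monoculture. Entries left out are derived
#: (senescent concentrations and efficiencies follow from the resorption
#: algebra); 0.0 encodes "no effect". NRE/PRE/RRE entries constrain the
#: monoculture senescent/green ratio, see :func:`default_species_params`.
DEFAULT_MIXTURE_EFFECTS = {
    ("RP", "RPAD"): {"GLNC": 0.0, "GLPC": 15.70, "SLPC": 0.0, "PRE": 10.73, "RRE": -12.05},
    ("RP", "RPAS"): {"GLNC": -6.41, "GLPC": 0.0, "SLNC": -14.44, "SLPC": -13.33},
    ("AD", "RPAD"): {
        "GLNC": 44.48, "GLPC": 35.23, "SLNC": 83.08, "SLPC": 66.67,
        "NRE": -29.93, "PRE": -29.35,
    },
    ("AS", "RPAS"): {
        "GLNC": 28.83, "GLPC": 14.29, "SLNC": 42.75, "SLPC": 22.41,
        "NRE": -12.21, "PRE": -9.31,
    },
}

#: Monoculture green-leaf anchors (GLNC, GLPC in g kg^-1). Synthetic
#: stand-ins at field-plausible levels: the legume runs N-rich.
DEFAULT_MONO_GREEN = {"RP": (28.0, 1.60), "AD": (16.0, 1.20), "AS": (18.0, 1.30)}

#: RP monoculture relative resorption efficiency anchor (< 100: P-limited,
#: as expected for an N2-fixer on calcareous loess). Fixes RP's true NRE
#: given its PRE, which the mixture-effect algebra determines.
DEFAULT_RP_MONO_RRE = 90.0

#: species -> mean/sd of tree structure: AH (m), DBH (cm), CA (m^2)
DEFAULT_STRUCTURE = {
    "RP": {"AH": (9.0, 1.2), "DBH": (12.0, 1.8), "CA": (10.0, 2.0)},
    "AD": {"AH": (4.5, 0.7), "DBH": (9.0, 1.4), "CA": (12.0, 2.5)},
    "AS": {"AH": (4.0, 0.6), "DBH": (8.0, 1.2), "CA": (11.0, 2.2)},
}

#: species -> mean/sd of leaf morphology: FW (g), LDMC (g g^-1, used to set
#: DW = FW x LDMC so dry never exceeds fresh mass), LT (mm), LA (cm^2)
DEFAULT_MORPH = {
    "RP": {"FW": (0.55, 0.08), "LDMC": (0.38, 0.03), "LT": (0.22, 0.03), "LA": (9.0, 1.5)},
    "AD": {"FW": (0.80, 0.10), "LDMC": (0.42, 0.03), "LT": (0.28, 0.03), "LA": (14.0, 2.0)},
    "AS": {"FW": (0.75, 0.10), "LDMC": (0.41, 0.03), "LT": (0.30, 0.03), "LA": (13.0, 2.0)},
}

#: per-plot topsoil parameters (mean, sd), calcareous loess defaults
DEFAULT_SOIL = {
    "pH": (8.4, 0.12),
    "BD_gcm3": (1.25, 0.07),
    "SOC_gkg": (6.5, 1.1),
    "TN_gkg": (0.65, 0.10),
    "TP_gkg": (0.60, 0.05),
    "AN_mgkg": (28.0, 4.5),
    "AP_mgkg": (3.2, 0.55),
}
#: texture composition means (sand, silt, clay, %) and Dirichlet concentration
DEFAULT_TEXTURE = (55.0, 35.0, 10.0)
DEFAULT_TEXTURE_CONC = 300.0


def solve_mono_ratio(d_green: float, d_senescent: float, d_eff: float) -> float:
    """Monoculture (senescent x MLCF / green) product implied by a delta triple.

    Given the percentage changes (mixture vs. monoculture) of the green mean,
    the senescent mean, and the resorption efficiency, the monoculture
    quantity r*M = SLC/GLC x MLCF is pinned down by

        (1 - a r M) = (1 + dE) (1 - r M),  a = (1+dS)/(1+dG),

    i.e. r M = dE / ((1 + dE) - a), with deltas as fractions. The
    monoculture efficiency is then 100 (1 - r M).
    """
    dg, ds, de = d_green / 100.0, d_senescent / 100.0, d_eff / 100.0
    a = (1.0 + ds) / (1.0 + dg)
    denom = (1.0 + de) - a
    if denom == 0:
        raise DesignError("degenerate delta triple: efficiency unconstrained")
    rm = de / denom
    if not 0 < rm < 1:
        raise DesignError(f"delta triple implies impossible senescent/green ratio {rm:.3f}")
    return rm


def default_species_params(
    mlcf: float = MLCF_ANGIOSPERM,
    mixture_effects: dict | None = None,
    mono_green: dict | None = None,
    rp_mono_rre: float = DEFAULT_RP_MONO_RRE,
) -> dict:
    """True cell means per (species, stand): GLNC, GLPC, SLNC, SLPC, NRE, PRE.

    Monoculture cells come from the green anchors plus senescent/green ratios
    solved from the calibrated effect triples; mixture cells apply the
    percent effects to the monoculture truth, deriving whichever of
    {senescent concentration, efficiency} the effect table leaves implicit.
    """
    effects = DEFAULT_MIXTURE_EFFECTS if mixture_effects is None else mixture_effects
    anchors = DEFAULT_MONO_GREEN if mono_green is None else mono_green

    rm = {}  # (species, nutrient) -> r*M of the monoculture
    # AD and AS: both nutrient triples fully printed in the effect table.
    for sp, mix in (("AD", "RPAD"), ("AS", "RPAS")):
        eff = effects[(sp, mix)]
        rm[(sp, "N")] = solve_mono_ratio(eff["GLNC"], eff["SLNC"], eff["NRE"])
        rm[(sp, "P")] = solve_mono_ratio(eff["GLPC"], eff["SLPC"], eff["PRE"])
    # RP: the P triple is constrained via the RPAD PRE effect; the N side is
    # anchored by the monoculture RRE (its NRE effect is only constrained
    # jointly with RRE, handled below).
    eff_rpad = effects[("RP", "RPAD")]
    rm[("RP", "P")] = solve_mono_ratio(eff_rpad["GLPC"], eff_rpad["SLPC"], eff_rpad["PRE"])
    pre_rp = 100.0 * (1.0 - rm[("RP", "P")])
    nre_rp = rp_mono_rre / 100.0 * pre_rp
    rm[("RP", "N")] = 1.0 - nre_rp / 100.0

    params: dict = {}
    for sp in ("RP", "AD", "AS"):
        glnc, glpc = anchors[sp]
        nre = 100.0 * (1.0 - rm[(sp, "N")])
        pre = 100.0 * (1.0 - rm[(sp, "P")])
        params[(sp, MONO_STAND[sp])] = {
            "GLNC": glnc,
            "GLPC": glpc,
            "SLNC": glnc * rm[(sp, "N")] / mlcf,
            "SLPC": glpc * rm[(sp, "P")] / mlcf,
            "NRE": nre,
            "PRE": pre,
        }

    for (sp, mix), eff in effects.items():
        mono = params[(sp, MONO_STAND[sp])]
        cell = {}
        cell["GLNC"] = mono["GLNC"] * (1.0 + eff.get("GLNC", 0.0) / 100.0)
        cell["GLPC"] = mono["GLPC"] * (1.0 + eff.get("GLPC", 0.0) / 100.0)
        for nutrient, g_key, s_key, e_key in (
            ("N", "GLNC", "SLNC", "NRE"),
            ("P", "GLPC", "SLPC", "PRE"),
        ):
            if s_key in eff:
                cell[s_key] = mono[s_key] * (1.0 + eff[s_key] / 100.0)
                cell[e_key] = (1.0 - cell[s_key] / cell[g_key] * mlcf) * 100.0
            else:
                # efficiency change given via e_key directly, or jointly via
                # RRE and the other nutrient's efficiency change
                if e_key in eff:
                    d_eff = eff[e_key]
                elif "RRE" in eff:
                    other = "PRE" if e_key == "NRE" else "NRE"
                    d_eff = (
                        (1.0 + eff["RRE"] / 100.0) * (1.0 + eff.get(other, 0.0) / 100.0)
                        - 1.0
                    ) * 100.0
                else:
                    d_eff = 0.0
                cell[e_key] = mono[e_key] * (1.0 + d_eff / 100.0)
                cell[s_key] = cell[g_key] * (1.0 - cell[e_key] / 100.0) / mlcf
        params[(sp, mix)] = cell
    return params


@dataclass
class TruthTable:
    """True cell means and the exact mixture-effect percentages they imply."""

    cells: pd.DataFrame  # index: species, stand_type; columns GLNC..PRE, RRE
    mlcf: float = MLCF_ANGIOSPERM

    @classmethod
    def from_params(cls, species_params: dict, mlcf: float) -> "TruthTable":
        rows = []
        for (sp, stand), cell in sorted(species_params.items()):
            row = {"species": sp, "stand_type": stand, **cell}
            row["RRE"] = cell["NRE"] / cell["PRE"] * 100.0
            row["limitation"] = classify_limitation(row["RRE"])
            rows.append(row)
        cells = pd.DataFrame(rows).set_index(["species", "stand_type"]).sort_index()
        return cls(cells=cells, mlcf=mlcf)

    def cell(self, species: str, stand_type: str) -> pd.Series:
        return self.cells.loc[(species, stand_type)]

    def deltas(self) -> pd.DataFrame:
        """Exact (mix - mono)/mono x 100 of the true means, per mixture cell."""
        rows = []
        for (sp, stand) in self.cells.index:
            mono = MONO_STAND[sp]
            if stand == mono:
                continue
            mix_cell, mono_cell = self.cell(sp, stand), self.cell(sp, mono)
            for q in ("GLNC", "GLPC", "SLNC", "SLPC", "NRE", "PRE", "RRE"):
                rows.append(
                    {
                        "species": sp,
                        "mixed_stand": stand,
                        "mono_stand": mono,
                        "quantity": q,
                        "delta_pct": delta_percent(mix_cell[q], mono_cell[q]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class StudyDesign:
    """Full parameterisation of a synthetic study.

    ``species_params`` maps (species, stand_type) to true cell means for
    GLNC/GLPC/SLNC/SLPC (g kg^-1) and NRE/PRE (%); the senescent means must
    equal the resorption inversion of the green means (checked). Noise CVs
    are multiplicative-lognormal coefficients of variation; ``plot_sd`` is
    the log-scale SD of an optional plot-level random intercept on nutrient
    concentrations (default 0: no within-plot correlation is assumed).
    """

    stand_composition: dict = field(
        default_factory=lambda: dict(DEFAULT_STAND_COMPOSITION)
    )
    n_plots_per_stand: int = 3
    n_trees_per_species_per_plot: int = 5
    species_params: dict = field(default_factory=default_species_params)
    cv_green: float = 0.10
    cv_senescent: float = 0.10
    plot_sd: float = 0.0
    structure_params: dict = field(default_factory=lambda: dict(DEFAULT_STRUCTURE))
    morph_params: dict = field(default_factory=lambda: dict(DEFAULT_MORPH))
    soil_params: dict = field(default_factory=lambda: dict(DEFAULT_SOIL))
    texture_pct: tuple = DEFAULT_TEXTURE
    texture_conc: float = DEFAULT_TEXTURE_CONC
    mlcf: float = MLCF_ANGIOSPERM
    seed: int = 0
    #: stand densities (trees ha^-1): metadata only, no computational role
    stand_density: dict = field(default_factory=dict)

    def validate(self) -> None:
        for stand, comp in self.stand_composition.items():
            if len(comp) not in (1, 2):
                raise DesignError(
                    f"stand {stand!r} lists {len(comp)} species; monocultures need "
                    "exactly one, mixtures exactly two"
                )
            for sp in comp:
                if sp not in self.structure_params:
                    raise DesignError(f"unknown species {sp!r} in stand {stand!r}")
                if (sp, stand) not in self.species_params:
                    raise DesignError(f"no species_params for cell ({sp!r}, {stand!r})")
        if self.n_plots_per_stand < 1 or self.n_trees_per_species_per_plot < 1:
            raise DesignError("plot and tree counts must be >= 1")
        if self.cv_green < 0 or self.cv_senescent < 0 or self.plot_sd < 0:
            raise DesignError("noise CVs and plot_sd must be non-negative")
        if not 0 < self.mlcf <= 1:
            raise DesignError("mlcf must lie in (0, 1]")
        for key, cell in self.species_params.items():
            for q in ("GLNC", "GLPC", "SLNC", "SLPC"):
                if not cell[q] > 0:
                    raise DesignError(f"non-positive true mean {q} in cell {key}")
            for q in ("NRE", "PRE"):
                if not 0 < cell[q] < 100:
                    raise DesignError(
                        f"true {q} in cell {key} must lie strictly in (0, 100)"
                    )
        if abs(sum(self.texture_pct) - 100.0) > 1e-9:
            raise DesignError("texture percentages must sum to 100")

    def truth(self) -> TruthTable:
        return TruthTable.from_params(self.species_params, self.mlcf)

    def design_hash(self) -> str:
        payload = {
            "stand_composition": {k: list(v) for k, v in self.stand_composition.items()},
            "n_plots_per_stand": self.n_plots_per_stand,
            "n_trees_per_species_per_plot": self.n_trees_per_species_per_plot,
            "species_params": {f"{sp}@{st}": v for (sp, st), v in sorted(self.species_params.items())},
            "cv_green": self.cv_green,
            "cv_senescent": self.cv_senescent,
            "plot_sd": self.plot_sd,
            "structure_params": self.structure_params,
            "morph_params": self.morph_params,
            "soil_params": self.soil_params,
            "texture_pct": list(self.texture_pct),
            "texture_conc": self.texture_conc,
            "mlcf": self.mlcf,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def default_design(**overrides) -> StudyDesign:
    """The calibrated default design (mixture effects switched on)."""
    design = StudyDesign(**overrides)
    design.validate()
    return design


def null_design(**overrides) -> StudyDesign:
    """A fully null design: every mixture cell equals its monoculture cell.

    Species still differ from one another (a species main effect remains),
    but stand type has no effect on any true mean — the reference condition
    for type-I-error studies of the stand and interaction terms.
    """
    params = default_species_params()
    for (sp, stand) in list(params):
        if stand != MONO_STAND[sp]:
            params[(sp, stand)] = dict(params[(sp, MONO_STAND[sp])])
    design = StudyDesign(species_params=params, **overrides)
    design.validate()
    return design


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Mean-exact lognormal draw: E[X] = mean, SD[X]/E[X] = cv."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, upper: float = np.inf) -> float:
    """Normal draw truncated to (0, upper], by rejection.

    The defaults keep means several SDs inside the support, so rejection is
    rare; the inverse-CDF fallback covers pathological parameterisations.
    """
    if sd == 0:
        return mean
    for _ in range(64):
        x = rng.normal(mean, sd)
        if 0.0 < x <= upper:
            return float(x)
    lo = stats.norm.cdf(0.0, mean, sd)
    hi = stats.norm.cdf(upper, mean, sd)
    return float(stats.norm.ppf(rng.uniform(lo, hi), mean, sd))


def _plot_rng(seed: int, stand_idx: int, plot_idx: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stand_idx, plot_idx]))


def _tree_rng(seed, stand_idx, plot_idx, species_idx, tree_idx) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed, stand_idx, plot_idx, species_idx, tree_idx])
    )


def generate_study(design: StudyDesign, seed: int | None = None):
    """Draw one dataset from a study design.

    Returns ``(Dataset, TruthTable)``. ``seed`` overrides ``design.seed``.
    Per-tree green concentrations are lognormal around the (plot-adjusted)
    true cell mean; senescent concentrations derive from the tree's *own*
    green value and the cell's true efficiency via the resorption inversion,
    times multiplicative senescent noise — so noise-free data recover the
    configured efficiencies exactly, tree by tree.
    """
    design.validate()
    if seed is None:
        seed = design.seed
    seed = int(seed)

    tree_rows: list[dict] = []
    soil_rows: list[dict] = []
    species_order = {sp: i for i, sp in enumerate(sorted(design.structure_params))}

    for stand_idx, (stand, comp) in enumerate(design.stand_composition.items()):
        for p in range(design.n_plots_per_stand):
            plot_id = f"{stand}-{p + 1}"
            prng = _plot_rng(seed, stand_idx, p)
            soil = {"plot_id": plot_id, "stand_type": stand}
            for key, (mean, sd) in design.soil_params.items():
                soil[key] = _truncnorm(prng, mean, sd)
            alpha = np.asarray(design.texture_pct) / 100.0 * design.texture_conc
            sa, si, cl = prng.dirichlet(alpha) * 100.0
            soil.update({"SA_pct": sa, "SI_pct": si, "CL_pct": cl})
            soil_rows.append({c: soil[c] for c in SOIL_COLUMNS})
            # plot-level multiplicative intercepts on N and P concentrations
            if design.plot_sd > 0:
                fac_n = float(prng.lognormal(-design.plot_sd**2 / 2, design.plot_sd))
                fac_p = float(prng.lognormal(-design.plot_sd**2 / 2, design.plot_sd))
            else:
                fac_n = fac_p = 1.0

            for sp in comp:
                cell = design.species_params[(sp, stand)]
                struct = design.structure_params[sp]
                morph = design.morph_params[sp]
                for t in range(design.n_trees_per_species_per_plot):
                    rng = _tree_rng(seed, stand_idx, p, species_order[sp], t)
                    ah = _truncnorm(rng, *struct["AH"])
                    dbh = _truncnorm(rng, *struct["DBH"])
                    ca = _truncnorm(rng, *struct["CA"])
                    fw = _truncnorm(rng, *morph["FW"])
                    ldmc = _truncnorm(rng, *morph["LDMC"], upper=1.0)
                    lt = _truncnorm(rng, *morph["LT"])
                    la = _truncnorm(rng, *morph["LA"])
                    glnc = _lognormal(rng, cell["GLNC"] * fac_n, design.cv_green)
                    glpc = _lognormal(rng, cell["GLPC"] * fac_p, design.cv_green)
                    slnc = (
                        glnc * (1.0 - cell["NRE"] / 100.0) / design.mlcf
                        * _lognormal(rng, 1.0, design.cv_senescent)
                    )
                    slpc = (
                        glpc * (1.0 - cell["PRE"] / 100.0) / design.mlcf
                        * _lognormal(rng, 1.0, design.cv_senescent)
                    )
                    tree_rows.append(
                        {
                            "tree_id": f"{plot_id}-{sp}-{t + 1}",
                            "stand_type": stand,
                            "species": sp,
                            "plot_id": plot_id,
                            "AH_m": ah,
                            "DBH_cm": dbh,
                            "CA_m2": ca,
                            "FW_g": fw,
                            "DW_g": fw * ldmc,
                            "LT_mm": lt,
                            "LA_cm2": la,
                            "GLNC_gkg": glnc,
                            "GLPC_gkg": glpc,
                            "SLNC_gkg": slnc,
                            "SLPC_gkg": slpc,
                        }
                    )

    trees = pd.DataFrame(tree_rows, columns=TREE_COLUMNS)
    soil = pd.DataFrame(soil_rows, columns=SOIL_COLUMNS)
    provenance = {
        "seed": seed,
        "design_hash": design.design_hash(),
        "generator": f"standmix {__version__}",
    }
    dataset = Dataset(trees=trees, soil=soil, provenance=provenance)
    dataset.validate()
    return dataset, design.truth()


# ---------------------------------------------------------------------------
# design (de)serialisation for the CLI config file

_SCALAR_FIELDS = (
    "n_plots_per_stand",
    "n_trees_per_species_per_plot",
    "cv_green",
    "cv_senescent",
    "plot_sd",
    "texture_conc",
    "mlcf",
    "seed",
)


def design_to_dict(design: StudyDesign) -> dict:
    return {
        "stand_composition": {k: list(v) for k, v in design.stand_composition.items()},
        **{f: getattr(design, f) for f in _SCALAR_FIELDS},
        "species_params": {
            f"{sp}@{st}": dict(v) for (sp, st), v in sorted(design.species_params.items())
        },
        "structure_params": design.structure_params,
        "morph_params": design.morph_params,
        "soil_params": {k: list(v) for k, v in design.soil_params.items()},
        "texture_pct": list(design.texture_pct),
        "stand_density": design.stand_density,
    }


def design_from_dict(payload: dict) -> StudyDesign:
    """Build a design from a config mapping; unspecified keys take defaults."""
    design = default_design()
    kwargs: dict = {}
    if "stand_composition" in payload:
        kwargs["stand_composition"] = {
            k: tuple(v) for k, v in payload["stand_composition"].items()
        }
    for f in _SCALAR_FIELDS:
        if f in payload:
            kwargs[f] = payload[f]
    if "species_params" in payload:
        params = {}
        for key, cell in payload["species_params"].items():
            sp, st = key.split("@")
            params[(sp, st)] = dict(cell)
        kwargs["species_params"] = params
    for f in ("structure_params", "morph_params", "stand_density"):
        if f in payload:
            kwargs[f] = payload[f]
    if "soil_params" in payload:
        kwargs["soil_params"] = {k: tuple(v) for k, v in payload["soil_params"].items()}
    if "texture_pct" in payload:
        kwargs["texture_pct"] = tuple(payload["texture_pct"])
    design = replace(design, **kwargs)
    design.validate()
    return design
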