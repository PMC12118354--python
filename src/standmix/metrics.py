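"""Leaf trait and nutrient-resorption metrics.

All quantities follow the conventions standard in plant stoichiometry work:

* SLA  — specific leaf area, one-sided area per dry mass (cm^2 g^-1)
* LDMC — leaf dry matter content, dry mass per fresh mass (g g^-1)
* LD   — leaf tissue density, dry mass per leaf volume (g cm^-3)
* NuRE — nutrient resorption efficiency (%), the fraction of N or P withdrawn
  from leaves before abscission, corrected for the dry-mass loss that occurs
  during senescence via a multiplicative mass-loss correction factor (MLCF;
  0.784 for angiosperms)
* RRE  — relative resorption efficiency, NRE/PRE x 100 (%): > 100 diagnoses
  N limitation of growth, < 100 P limitation, exactly 100 co-limitation.

Functions accept scalars or numpy arrays and broadcast; domain violations
raise :class:`~standmix.exceptions.DomainError`.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import DomainError, MissingCellError

#: Angiosperm mass-loss correction factor (dry-mass loss during senescence).
MLCF_ANGIOSPERM = 0.784

N_LIMITED = "N-limited"
P_LIMITED = "P-limited"
CO_LIMITED = "co-limited"
INDETERMINATE = "indeterminate"


def _as_array(x):
    return np.asarray(x, dtype=float)


def _maybe_scalar(x, template):
    if np.isscalar(template) or np.ndim(template) == 0:
        return float(x)
    return x


def compute_sla(la, dw):
    """Specific leaf area: one-sided leaf area (cm^2) over dry mass (g)."""
    la_a, dw_a = _as_array(la), _as_array(dw)
    if np.any(la_a <= 0) or np.any(dw_a <= 0):
        raise DomainError("SLA requires LA > 0 and DW > 0")
    return _maybe_scalar(la_a / dw_a, la if np.ndim(la) else dw)


def compute_ldmc(dw, fw):
    """Leaf dry matter content: dry over fresh mass, in (0, 1]."""
    dw_a, fw_a = _as_array(dw), _as_array(fw)
    if np.any(dw_a <= 0):
        raise DomainError("LDMC requires DW > 0")
    if np.any(dw_a > fw_a):
        raise DomainError("LDMC requires FW >= DW (dry mass cannot exceed fresh mass)")
    return _maybe_scalar(dw_a / fw_a, dw if np.ndim(dw) else fw)


def compute_ld(dw, lt_mm, la):
    """Leaf tissue density, g cm^-3.

    Volume is thickness x one-sided area; thickness is measured in mm and
    converted to cm here so the density comes out in g cm^-3.
    """
    dw_a, lt_a, la_a = _as_array(dw), _as_array(lt_mm), _as_array(la)
    if np.any(dw_a <= 0) or np.any(lt_a <= 0) or np.any(la_a <= 0):
        raise DomainError("LD requires DW, LT and LA all > 0")
    return _maybe_scalar(dw_a / ((lt_a / 10.0) * la_a), dw if np.ndim(dw) else lt_mm)


def compute_nure(green, senescent, mlcf: float = MLCF_ANGIOSPERM):
    """Nutrient resorption efficiency (%) with mass-loss correction.

    NuRE = (1 - senescent/green x MLCF) x 100.

    Negative values (apparent nutrient accretion during senescence) are
    returned as-is rather than clipped; callers that tabulate NuRE flag them.
    """
    g, s = _as_array(green), _as_array(senescent)
    if np.any(g <= 0):
        raise DomainError("NuRE requires green concentration > 0")
    if np.any(s < 0):
        raise DomainError("NuRE requires senescent concentration >= 0")
    if not 0 < mlcf <= 1:
        raise DomainError("MLCF must lie in (0, 1]")
    out = (1.0 - s / g * mlcf) * 100.0
    return _maybe_scalar(out, green if np.ndim(green) else senescent)


def compute_rre(nre, pre):
    """Relative resorption efficiency and the growth-limitation label.

    RRE = NRE/PRE x 100. RRE > 100 -> N limits growth; RRE < 100 -> P limits
    growth; RRE == 100 (exact) -> N and P co-limit. If either efficiency is
    negative the ratio is still returned but the label is "indeterminate",
    because the limitation rule is defined for resorbing leaves only.
    """
    if pre == 0:
        raise DomainError("RRE undefined: PRE is 0")
    rre = nre / pre * 100.0
    if nre < 0 or pre < 0:
        warnings.warn(
            "negative resorption efficiency: limitation label is indeterminate",
            stacklevel=2,
        )
        return rre, INDETERMINATE
    return rre, classify_limitation(rre)


def classify_limitation(rre: float) -> str:
    """Map an RRE value (%) onto the limitation trichotomy (exact at 100)."""
    if rre > 100.0:
        return N_LIMITED
    if rre < 100.0:
        return P_LIMITED
    return CO_LIMITED


def delta_percent(mix_mean, mono_mean):
    """Signed percentage change of a mixed-stand mean vs. its monoculture.

    delta = (mix - mono)/mono x 100. The monoculture is always the
    denominator, so the quantity is not antisymmetric under swapping roles;
    instead mono x (1 + delta/100) reconstructs the mixed-stand mean.
    """
    mono_a = _as_array(mono_mean)
    if np.any(mono_a == 0):
        raise DomainError("delta undefined: monoculture mean is 0")
    out = (_as_array(mix_mean) - mono_a) / mono_a * 100.0
    return _maybe_scalar(out, mix_mean if np.ndim(mix_mean) else mono_mean)


def add_trait_columns(trees: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the tree table with SLA, LDMC and LD columns added."""
    out = trees.copy()
    out["SLA"] = compute_sla(out["LA_cm2"].to_numpy(), out["DW_g"].to_numpy())
    out["LDMC"] = compute_ldmc(out["DW_g"].to_numpy(), out["FW_g"].to_numpy())
    out["LD"] = compute_ld(
        out["DW_g"].to_numpy(), out["LT_mm"].to_numpy(), out["LA_cm2"].to_numpy()
    )
    return out


def stand_species_means(data, variable: str) -> pd.DataFrame:
    """Per species x stand-type summary (mean, n, sd, se) of one variable.

    ``data`` is either a Dataset or a tree table. Cells absent from the
    design are absent from the result (never imputed as zero); a single-tree
    cell has NaN sd/se. Requesting a cell that does not exist downstream is
    the caller's responsibility — use :func:`require_cell`.
    """
    trees = data.trees if hasattr(data, "trees") else data
    if variable not in trees.columns:
        raise KeyError(f"variable {variable!r} not in tree table")
    grouped = trees.groupby(["species", "stand_type"], sort=True)[variable]
    table = grouped.agg(mean="mean", n="size", sd=lambda s: s.std(ddof=1))
    table["se"] = table["sd"] / np.sqrt(table["n"])
    return table.reset_index()


def require_cell(means: pd.DataFrame, species: str, stand_type: str) -> pd.Series:
    """Fetch one species x stand row from a means table or raise."""
    hit = means[(means["species"] == species) & (means["stand_type"] == stand_type)]
    if hit.empty:
        raise MissingCellError(f"no trees for species {species!r} in stand {stand_type!r}")
    return hit.iloc[0]


def resorption_table(
    data,
    level: str = "tree",
    mlcf: float = MLCF_ANGIOSPERM,
) -> pd.DataFrame:
    """NRE/PRE/RRE and limitation labels over a dataset.

    level="tree" computes NuRE per tree from that tree's own green/senescent
    pair (the default: it preserves the within-tree pairing of the sampled
    leaves); level="stand" computes NuRE from the species x stand mean
    concentrations (ratio of means). Both carry RRE and a limitation label;
    trees with negative NuRE are flagged ``accretion`` and labelled
    indeterminate.
    """
    trees = data.trees if hasattr(data, "trees") else data
    if level == "tree":
        base = trees[["tree_id", "species", "stand_type"]].copy()
        base["NRE"] = compute_nure(
            trees["GLNC_gkg"].to_numpy(), trees["SLNC_gkg"].to_numpy(), mlcf
        )
        base["PRE"] = compute_nure(
            trees["GLPC_gkg"].to_numpy(), trees["SLPC_gkg"].to_numpy(), mlcf
        )
    elif level == "stand":
        cells = (
            trees.groupby(["species", "stand_type"], sort=True)[
                ["GLNC_gkg", "GLPC_gkg", "SLNC_gkg", "SLPC_gkg"]
            ]
            .mean()
            .reset_index()
        )
        base = cells[["species", "stand_type"]].copy()
        base["NRE"] = compute_nure(
            cells["GLNC_gkg"].to_numpy(), cells["SLNC_gkg"].to_numpy(), mlcf
        )
        base["PRE"] = compute_nure(
            cells["GLPC_gkg"].to_numpy(), cells["SLPC_gkg"].to_numpy(), mlcf
        )
    else:
        raise ValueError(f"level must be 'tree' or 'stand', got {level!r}")

    if np.any(base["PRE"].to_numpy() == 0):
        bad = base.loc[base["PRE"] == 0].index[0]
        raise DomainError(f"RRE undefined at row {bad}: PRE is 0")
    base["RRE"] = base["NRE"] / base["PRE"] * 100.0
    base["accretion"] = (base["NRE"] < 0) | (base["PRE"] < 0)
    base["limitation"] = np.select(
        [base["accretion"], base["RRE"] > 100.0, base["RRE"] < 100.0],
        [INDETERMINATE, N_LIMITED, P_LIMITED],
        default=CO_LIMITED,
    )
    base["mlcf_used"] = mlcf
    return base
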