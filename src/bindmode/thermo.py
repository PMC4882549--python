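"""Thermodynamic conversions between K_i, binding free energy and fold-change.

Conversions use dG = RT ln(K_i [M]) and ddG = RT ln(FC) with R = 1.9872e-3
kcal/(mol K).  The default temperature is 298.15 K — the convention under
which published two-decimal affinity tables for the hNET/sNRI systems
reproduce — while simulations are typically run at 310 K; both are plain
parameters.  A mutation is classed "sensitive" when it shifts potency by at
least five-fold in either direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .ff_energy import R_KCAL

#: default temperature (K) for RT ln conversions
T_CONVERSION = 298.15

#: fold-change at or above which a mutation counts as sensitive
SENSITIVITY_FOLD = 5.0


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention of printed energy tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def dg_from_ki(ki_nm: float, temperature: float = T_CONVERSION) -> float:
    """Binding free energy (kcal/mol) from an inhibition constant in nM."""
    if ki_nm <= 0:
        raise ValueError("K_i must be positive")
    return R_KCAL * temperature * math.log(ki_nm * 1e-9)


def ddg_vs_reference(dg: dict[str, float], reference: str) -> dict[str, float]:
    """Relative binding free energies against a reference ligand.

    ``ddG_ligand = dG_ligand - dG_reference``; the reference maps to 0.
    """
    if reference not in dg:
        raise KeyError(f"reference ligand {reference!r} not in table")
    ref = dg[reference]
    return {lig: val - ref for lig, val in dg.items()}


def fc_ddg_convert(
    value: float, direction: str, temperature: float = T_CONVERSION
) -> float:
    """Convert between ddG (kcal/mol) and fold-change of potency.

    ``FC = exp(ddG/RT)`` and ``ddG = RT ln(FC)`` are exact mutual inverses.
    """
    rt = R_KCAL * temperature
    if direction == "ddg_to_fc":
        return math.exp(value / rt)
    if direction == "fc_to_ddg":
        if value <= 0:
            raise ValueError("fold-change must be positive")
        return rt * math.log(value)
    raise ValueError("direction must be 'ddg_to_fc' or 'fc_to_ddg'")


def classify_sensitivity(fc: float, threshold: float = SENSITIVITY_FOLD) -> str:
    """'sensitive' when max(FC, 1/FC) >= threshold (loss or gain of potency)."""
    if fc <= 0:
        raise ValueError("fold-change must be positive")
    return "sensitive" if max(fc, 1.0 / fc) >= threshold else "non-sensitive"


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation of two equally long series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two series of equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


# ---------------------------------------------------------------------------
# Records and table builders
# ---------------------------------------------------------------------------


@dataclass
class AffinityRecord:
    """One ligand's experimental and computed binding thermodynamics."""

    ligand: str
    ki_nm: float
    dg_exp: float
    dg_calc: float
    ddg_exp: float
    ddg_calc: float


@dataclass
class MutationResult:
    """A mutation's computed ddG, its fold-change and sensitivity class."""

    system: str
    ddg_calc: float
    fc_calc: float
    fc_exp: float | None
    ddg_exp: float | None
    sensitivity: str


def affinity_table(
    ki_by_ligand: dict[str, float],
    dg_calc_by_ligand: dict[str, float],
    reference: str,
    temperature: float = T_CONVERSION,
) -> list[AffinityRecord]:
    """Build the experimental-vs-computed affinity comparison.

    K_i values (nM) are converted to dG_exp; both dG columns are then
    referenced to ``reference`` to give ddG columns suitable for correlation.
    """
    dg_exp = {lig: dg_from_ki(ki, temperature) for lig, ki in ki_by_ligand.items()}
    ddg_exp = ddg_vs_reference(dg_exp, reference)
    ddg_calc = ddg_vs_reference(dg_calc_by_ligand, reference)
    return [
        AffinityRecord(
            ligand=lig,
            ki_nm=ki_by_ligand[lig],
            dg_exp=dg_exp[lig],
            dg_calc=dg_calc_by_ligand[lig],
            ddg_exp=ddg_exp[lig],
            ddg_calc=ddg_calc[lig],
        )
        for lig in ki_by_ligand
    ]


def mutation_table(
    ddg_calc_by_system: dict[str, float],
    fc_exp_by_system: dict[str, float] | None = None,
    temperature: float = T_CONVERSION,
    threshold: float = SENSITIVITY_FOLD,
) -> list[MutationResult]:
    """Fold-changes and sensitivity classes from computed mutation ddG values."""
    fc_exp_by_system = fc_exp_by_system or {}
    out = []
    for system, ddg in ddg_calc_by_system.items():
        fc = fc_ddg_convert(ddg, "ddg_to_fc", temperature)
        fc_exp = fc_exp_by_system.get(system)
        out.append(
            MutationResult(
                system=system,
                ddg_calc=ddg,
                fc_calc=fc,
                fc_exp=fc_exp,
                ddg_exp=(
                    fc_ddg_convert(fc_exp, "fc_to_ddg", temperature)
                    if fc_exp is not None
                    else None
                ),
                sensitivity=classify_sensitivity(fc, threshold),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Published reference data: sNRIs binding the human norepinephrine transporter
# ---------------------------------------------------------------------------

#: Median experimental inhibition constants (nM) for six sNRIs at hNET.
HNET_KI_NM: dict[str, float] = {
    "atomoxetine": 5.00,
    "maprotiline": 7.00,
    "nisoxetine": 1.60,
    "talopram": 2.90,
    "(S,S)-reboxetine": 0.08,
    "viloxazine": 73.00,
}

#: MM/GBSA binding free energies (kcal/mol) from 500-snapshot MD ensembles.
HNET_DG_MMGBSA: dict[str, float] = {
    "atomoxetine": -41.42,
    "maprotiline": -40.21,
    "nisoxetine": -46.05,
    "talopram": -42.47,
    "(S,S)-reboxetine": -47.67,
    "viloxazine": -37.48,
}

#: Reference ligand for relative free energies.
HNET_REFERENCE_LIGAND = "viloxazine"

#: Published two-decimal relative free energies (kcal/mol), experimental and
#: computed, for the correlation check.  Listed in the HNET_KI_NM order.
HNET_DDG_PRINTED: dict[str, tuple[float, float]] = {
    "atomoxetine": (-1.60, -3.94),
    "maprotiline": (-1.39, -2.73),
    "nisoxetine": (-2.26, -8.57),
    "talopram": (-1.91, -4.99),
    "(S,S)-reboxetine": (-4.04, -10.19),
    "viloxazine": (0.00, 0.00),
}

#: Computed ddG (kcal/mol) for sNRIs against the hDAT-like sextuple mutant of
#: hNET (A145S-Y151F-I315V-F316C-S420A-A426S), with experimental median
#: fold-changes where measured.
HDAT_LIKE_MUTATION_DDG: dict[str, float] = {
    "talopram": 3.70,
    "nisoxetine": 2.89,
    "atomoxetine": 1.15,
    "reboxetine": 0.47,
    "maprotiline": 2.45,
    "viloxazine": 1.09,
}

HDAT_LIKE_MUTATION_FC_EXP: dict[str, float] = {
    "talopram": 207.00,
    "nisoxetine": 168.42,
    "atomoxetine": 27.87,
    "reboxetine": 10.27,
}

#: Computed ddG (kcal/mol) for single-point hNET mutants, keyed
#: "<ligand>/<mutation>", with experimental median fold-changes.
POINT_MUTATION_DDG: dict[str, float] = {
    "atomoxetine/F72Y": -0.03,
    "atomoxetine/N153S": -0.31,
    "atomoxetine/F323Y": 1.93,
    "atomoxetine/S419T": 1.27,
    "maprotiline/F72Y": -0.31,
    "maprotiline/N153S": 0.05,
    "maprotiline/F323Y": 0.96,
    "maprotiline/S419T": 1.36,
}

POINT_MUTATION_FC_EXP: dict[str, float] = {
    "atomoxetine/F72Y": 0.78,
    "atomoxetine/N153S": 2.33,
    "atomoxetine/F323Y": 3.89,
    "atomoxetine/S419T": 12.67,
    "maprotiline/F72Y": 0.59,
    "maprotiline/N153S": 2.34,
    "maprotiline/F323Y": 4.97,
    "maprotiline/S419T": 5.88,
}
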