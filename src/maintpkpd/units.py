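"""Unit conversions for erythrocyte drug concentrations.

Metabolite concentrations in red blood cells are conventionally reported
per amount of hemoglobin (nmol/mmol Hb).  The compartment models work in
molar concentration (µmol/L of packed red cells), so measurements are
converted using the molarity of hemoglobin in erythrocytes:

    [Hb] = 330 g/L / 64458 g/mol = 5.1196 mmol/L

hence 1 nmol/mmol Hb = 5.1196 nmol/L = 5.1196e-3 µmol/L.
"""

from __future__ import annotations

#: Hemoglobin concentration inside erythrocytes [g/L].
HB_CONCENTRATION_G_PER_L = 330.0
#: Molecular weight of hemoglobin [g/mol].
HB_MOLECULAR_WEIGHT = 64458.0
#: Molar Hb concentration [mmol/L].
HB_MOLARITY_MMOL_PER_L = HB_CONCENTRATION_G_PER_L / HB_MOLECULAR_WEIGHT * 1000.0

#: Molecular weights of the two drugs [g/mol].
MW_6MP = 152.18
MW_MTX = 454.44


def convert_ery_concentration(value_nmol_per_mmol_hb: float) -> float:
    """Convert an erythrocyte concentration from nmol/mmol Hb to µmol/L.

    Parameters
    ----------
    value_nmol_per_mmol_hb : float
        Concentration in nmol per mmol hemoglobin.  Must be >= 0.

    Returns
    -------
    float
        Concentration in µmol/L (of erythrocyte volume).
    """
    if value_nmol_per_mmol_hb < 0:
        raise ValueError(
            f"erythrocyte concentration must be non-negative, "
            f"got {value_nmol_per_mmol_hb!r}"
        )
    return value_nmol_per_mmol_hb * HB_MOLARITY_MMOL_PER_L * 1e-3


def mg_to_umol(amount_mg: float, molecular_weight: float) -> float:
    """Convert a drug amount from mg to µmol."""
    return amount_mg / molecular_weight * 1000.0


def bsa_mosteller(height_cm: float, weight_kg: float) -> float:
    """Body surface area [m²] by the Mosteller formula sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    return (height_cm * weight_kg / 3600.0) ** 0.5
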