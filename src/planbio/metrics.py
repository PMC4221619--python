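"""Physical plan-quality indices computed from DVHs.

Conventions: Vx% / VxGy report the percentage of structure volume receiving
at least the stated dose; Dx% is the minimum dose to the hottest x% of the
volume, so D2% proxies the maximum and D98% the minimum structure dose.
The conformation number CN (Van't Riet) multiplies target coverage by the
healthy-tissue selectivity of the prescription isodose; the homogeneity
index HI = (D2% - D98%) / D50% is zero for a perfectly uniform target dose.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .dvh import DVH

__all__ = [
    "ConformityInputs",
    "conformation_number",
    "homogeneity_index",
    "target_metrics",
    "oar_metrics",
]


@dataclass(frozen=True)
class ConformityInputs:
    """Volumes (cm^3) entering the conformation number.

    v_t_ref : target volume receiving at least the reference dose.
    v_t     : physical target volume.
    v_ref   : total tissue volume receiving at least the reference dose.
    """

    v_t_ref: float
    v_t: float
    v_ref: float

    def __post_init__(self) -> None:
        if not self.v_t > 0:
            raise ValueError("target volume must be positive")
        if self.v_t_ref < 0:
            raise ValueError("covered target volume must be nonnegative")
        if self.v_t_ref > self.v_t * (1 + 1e-12):
            raise ValueError("covered target volume exceeds target volume")
        if self.v_t_ref > self.v_ref * (1 + 1e-12):
            raise ValueError("covered target volume exceeds reference isodose volume")


def conformation_number(c: ConformityInputs) -> float:
    """CN = (V_T,ref / V_T) * (V_T,ref / V_ref), in [0, 1].

    1 is ideal conformity (prescription isodose exactly fills the target),
    0 is total absence of conformity.
    """
    if c.v_t_ref == 0:
        return 0.0
    if c.v_ref == 0:
        raise ValueError("v_ref is zero while covered target volume is positive")
    return (c.v_t_ref / c.v_t) * (c.v_t_ref / c.v_ref)


def homogeneity_index(dvh: DVH) -> float:
    """HI = (D2% - D98%) / D50%; lower is more homogeneous."""
    d50 = dvh.dose_at_volume_fraction(0.50)
    if d50 <= 0:
        raise ValueError("D50% is zero; homogeneity index undefined")
    d2 = dvh.dose_at_volume_fraction(0.02)
    d98 = dvh.dose_at_volume_fraction(0.98)
    return (d2 - d98) / d50


def target_metrics(dvh: DVH, prescription: float,
                   conformity: Optional[ConformityInputs] = None) -> dict[str, float]:
    """Standard target indices at a given prescription dose (Gy).

    Returns mean/max/min dose, the D2/D50/D98 percent-volume doses, the
    coverage and hot-spot volumes V95%/V107%/V110% (percent scale), HI, and
    CN when conformity volumes are supplied.
    """
    if not prescription > 0:
        raise ValueError("prescription dose must be positive")
    out = {
        "mean": dvh.mean_dose(),
        "dmax": dvh.max_dose(),
        "dmin": dvh.min_dose(),
        "d2pct": dvh.dose_at_volume_fraction(0.02),
        "d50pct": dvh.dose_at_volume_fraction(0.50),
        "d98pct": dvh.dose_at_volume_fraction(0.98),
        "v95pct": 100.0 * dvh.volume_fraction_at_dose(0.95 * prescription),
        "v107pct": 100.0 * dvh.volume_fraction_at_dose(1.07 * prescription),
        "v110pct": 100.0 * dvh.volume_fraction_at_dose(1.10 * prescription),
        "hi": homogeneity_index(dvh),
    }
    if conformity is not None:
        out["cn"] = conformation_number(conformity)
    return out


def oar_metrics(dvh: DVH) -> dict[str, float]:
    """Standard organ-at-risk indices: D1%/D5%, mean/max, V30/40/50Gy (%)."""
    return {
        "mean": dvh.mean_dose(),
        "dmax": dvh.max_dose(),
        "d1pct": dvh.dose_at_volume_fraction(0.01),
        "d5pct": dvh.dose_at_volume_fraction(0.05),
        "v30gy": 100.0 * dvh.volume_fraction_at_dose(30.0),
        "v40gy": 100.0 * dvh.volume_fraction_at_dose(40.0),
        "v50gy": 100.0 * dvh.volume_fraction_at_dose(50.0),
    }
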