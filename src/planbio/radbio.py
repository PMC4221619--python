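"""Dose-response models: EQD2, Poisson-LQ response, TCP, relative-seriality
NTCP, generalized EUD and the complication-free tumour control probability P+.

The sigmoid dose-response adopted throughout is the Poisson (Kallman) form

    P(D) = 2 ** ( -exp( e * gamma * (1 - D / D50) ) )

with D50 the uniform dose giving 50% response and gamma the normalised
dose-response gradient; by construction P(D50) = 1/2 exactly and the
normalised slope at D50 is (e * ln2 / 2) * gamma.  Heterogeneous dose
distributions enter through the DVH: tumour control multiplies the per-bin
response in relative-volume weights (voxel independence), while normal
tissues use the relative-seriality architecture parameter ``s`` to
interpolate between parallel (s -> 0) and serial (large s) behaviour.

Physical bin doses are converted to the equivalent dose in 2-Gy fractions,

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),  d = D / n_fractions,

per bin before evaluating any response, unless the caller disables it.
All probability products are accumulated as sums of logs; probabilities
below ~1e-300 underflow to exactly 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq

from .dvh import DVH, uniform_dvh

__all__ = [
    "DoseResponseParams",
    "FractionationScheme",
    "ParamLibrary",
    "eqd2",
    "poisson_response",
    "tcp_poisson",
    "ntcp_relative_seriality",
    "geud",
    "p_plus",
    "invert_uniform_response",
]

_E = math.e
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class DoseResponseParams:
    """One dose-response parameter row.

    d50 : uniform dose (Gy) producing 50% response probability.
    gamma : dimensionless normalised dose-response gradient.
    alpha_beta : LQ fractionation-sensitivity ratio (Gy).
    seriality : relative-seriality parameter s (> 0); absent for tumour rows.
    endpoint : free-text endpoint label (e.g. "xerostomia").
    """

    d50: float
    gamma: float
    alpha_beta: float
    seriality: Optional[float] = None
    endpoint: str = ""

    def __post_init__(self) -> None:
        if not self.d50 > 0:
            raise ValueError("d50 must be positive")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if not self.alpha_beta > 0:
            raise ValueError("alpha/beta must be positive")
        if self.seriality is not None and not self.seriality > 0:
            raise ValueError("seriality must be positive when present")


@dataclass(frozen=True)
class FractionationScheme:
    """Number of (daily) fractions delivering the plan."""

    n_fractions: int

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise ValueError("n_fractions must be a positive integer")


def eqd2(total_dose, fx: FractionationScheme, alpha_beta: float):
    """Equivalent dose in 2-Gy fractions for a (per-bin) total dose.

    Each bin's total dose is assumed delivered evenly over all fractions,
    so the per-fraction dose is ``total_dose / n_fractions``.
    Array-valued ``total_dose`` is supported.
    """
    if not alpha_beta > 0:
        raise ValueError("alpha/beta must be positive")
    d = np.asarray(total_dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("total dose must be nonnegative")
    per_fraction = d / fx.n_fractions
    out = d * (per_fraction + alpha_beta) / (2.0 + alpha_beta)
    return out if out.ndim else float(out)


def _log_response(d, p: DoseResponseParams):
    """ln P(D) of the Poisson sigmoid, array-safe."""
    d = np.asarray(d, dtype=float)
    with np.errstate(over="ignore"):
        out = -_LN2 * np.exp(_E * p.gamma * (1.0 - d / p.d50))
    return out


def poisson_response(d_eqd2, p: DoseResponseParams):
    """Response probability P(D) at uniform (EQD2-scale) dose."""
    d = np.asarray(d_eqd2, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be nonnegative")
    out = np.exp(_log_response(d, p))
    return out if out.ndim else float(out)


def _bin_doses(dvh: DVH, p: DoseResponseParams,
               fx: Optional[FractionationScheme], use_eqd2: bool):
    d = dvh.as_differential()
    mids = d.midpoints
    if use_eqd2:
        if fx is None:
            raise ValueError("fractionation scheme required for EQD2 conversion")
        mids = eqd2(mids, fx, p.alpha_beta)
    return d, np.asarray(mids, dtype=float)


def tcp_poisson(dvh: DVH, p: DoseResponseParams,
                fx: Optional[FractionationScheme] = None,
                use_eqd2: bool = True) -> float:
    """Tumour control probability of a target DVH.

    TCP = prod_i P(EQD2(D_i)) ** v_i over DVH bins, computed in log space.
    """
    d, mids = _bin_doses(dvh, p, fx, use_eqd2)
    occ = d.volume > 0
    if not np.any(occ):
        raise ValueError("DVH carries no volume")
    log_tcp = float(d.volume[occ] @ _log_response(mids[occ], p))
    return math.exp(log_tcp) if log_tcp > -745 else 0.0


def ntcp_relative_seriality(dvh: DVH, p: DoseResponseParams,
                            fx: Optional[FractionationScheme] = None,
                            use_eqd2: bool = True) -> float:
    """Relative-seriality NTCP of an organ-at-risk DVH.

    NTCP = [ 1 - prod_i (1 - P_i^s)^{v_i} ] ^ (1/s), with P_i the per-bin
    Poisson response.  For a uniform dose this collapses to P(D) for any s.
    """
    if p.seriality is None:
        raise ValueError("seriality parameter s required for relative-seriality NTCP")
    s = p.seriality
    d, mids = _bin_doses(dvh, p, fx, use_eqd2)
    occ = d.volume > 0
    if not np.any(occ):
        raise ValueError("DVH carries no volume")
    log_p = _log_response(mids[occ], p)          # ln P_i
    p_s = np.exp(s * log_p)                      # P_i^s
    with np.errstate(divide="ignore"):
        log_one_minus = np.log1p(-np.clip(p_s, 0.0, 1.0))
    inner = float(d.volume[occ] @ log_one_minus)  # ln prod (1-P_i^s)^v_i
    if np.isneginf(inner):
        return 1.0
    # 1 - exp(inner), kept accurate when inner ~ 0
    one_minus_prod = -math.expm1(inner)
    if one_minus_prod <= 0.0:
        return 0.0
    return float(one_minus_prod ** (1.0 / s))


def geud(dvh: DVH, a_param: float, *, use_eqd2: bool = False,
         fx: Optional[FractionationScheme] = None,
         alpha_beta: Optional[float] = None) -> float:
    """Generalized equivalent uniform dose, the power mean (sum v D^A)^(1/A).

    A > 1 emphasises hot spots, A < 1 cold spots, A = 1 is the mean dose.
    Physical-dose scale by default; set ``use_eqd2`` (with ``fx`` and
    ``alpha_beta``) to transform bin doses first.
    """
    if a_param == 0:
        raise ValueError("a_param must be nonzero")
    d = dvh.as_differential()
    mids = d.midpoints
    if use_eqd2:
        if fx is None or alpha_beta is None:
            raise ValueError("fx and alpha_beta required when use_eqd2 is set")
        mids = np.asarray(eqd2(mids, fx, alpha_beta))
    occ = d.volume > 0
    mids, v = mids[occ], d.volume[occ]
    if a_param < 0 and np.any(mids <= 0):
        raise ValueError("zero-dose bin with negative A")
    # scale by an occupied dose to keep the powers in range
    scale = float(mids.max() if a_param > 0 else mids.min())
    ratio = mids / scale
    return float(scale * (v @ ratio ** a_param) ** (1.0 / a_param))


def p_plus(tcp: float, ntcps: Sequence[float] = ()) -> float:
    """Probability of complication-free tumour control.

    Combines one TCP with any number of NTCPs assuming independence:
    P+ = TCP * prod_j (1 - NTCP_j).
    """
    vals = [tcp, *ntcps]
    for v in vals:
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"probability {v!r} outside [0, 1]")
    out = tcp
    for n in ntcps:
        out *= 1.0 - n
    return float(out)


def invert_uniform_response(target_prob: float, p: DoseResponseParams,
                            model: str = "tcp", xtol: float = 1e-6) -> float:
    """Uniform EQD2-scale dose at which the model response equals target_prob.

    Evaluates the chosen model on a narrow single-bin DVH (so the whole
    DVH machinery, not just the sigmoid, is exercised) and root-finds on
    [0, 3*D50] by Brent's method.  At 0.5 this recovers D50 for both models.
    """
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target probability must lie strictly in (0, 1)")
    if model == "tcp":
        def f(d):
            return tcp_poisson(uniform_dvh(d, 1e-6), p, use_eqd2=False) - target_prob
    elif model == "ntcp":
        def f(d):
            return ntcp_relative_seriality(uniform_dvh(d, 1e-6), p,
                                           use_eqd2=False) - target_prob
    else:
        raise ValueError("model must be 'tcp' or 'ntcp'")
    lo, hi = 0.0, 3.0 * p.d50
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target probability not bracketed on [0, 3*D50]")
    return float(brentq(f, lo, hi, xtol=xtol))


class ParamLibrary:
    """Per-structure dose-response parameter sets plus staged tumour rows.

    Mirrors the clinical parameter table shipped with the package: one
    relative-seriality NTCP row per organ-at-risk class and three TCP rows
    selected by disease stage (early = stage I/II, T3, stage 4).
    """

    def __init__(self, tcp_rows: dict[str, DoseResponseParams],
                 ntcp_rows: dict[str, DoseResponseParams]):
        self._tcp = dict(tcp_rows)
        self._ntcp = dict(ntcp_rows)

    @classmethod
    def from_yaml(cls, path) -> "ParamLibrary":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_mapping(raw)

    @classmethod
    def default(cls) -> "ParamLibrary":
        from importlib.resources import files

        raw = yaml.safe_load(files("planbio.data").joinpath("dose_response.yaml").read_text())
        return cls._from_mapping(raw)

    @classmethod
    def _from_mapping(cls, raw: dict) -> "ParamLibrary":
        def row(entry):
            return DoseResponseParams(
                d50=float(entry["d50"]), gamma=float(entry["gamma"]),
                alpha_beta=float(entry["alpha_beta"]),
                seriality=(float(entry["seriality"])
                           if entry.get("seriality") is not None else None),
                endpoint=str(entry.get("endpoint", "")))
        return cls({k: row(v) for k, v in raw.get("tcp", {}).items()},
                   {k: row(v) for k, v in raw.get("ntcp", {}).items()})

    def tcp(self, stage: str) -> DoseResponseParams:
        """TCP row for a stage key: 'early', 't3' or 'stage4'."""
        try:
            return self._tcp[stage]
        except KeyError:
            raise KeyError(f"no TCP parameter row for stage {stage!r}") from None

    def ntcp(self, structure: str) -> DoseResponseParams:
        try:
            return self._ntcp[structure]
        except KeyError:
            raise KeyError(f"no NTCP parameter row for structure {structure!r}") from None

    def has_ntcp(self, structure: str) -> bool:
        return structure in self._ntcp

    @property
    def tcp_stages(self) -> list[str]:
        return list(self._tcp)

    @property
    def ntcp_structures(self) -> list[str]:
        return list(self._ntcp)
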