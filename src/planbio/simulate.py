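"""Seeded generator of paired two-arm NPC-like DVH cohorts.

The generator emulates the *statistical* structure of a paired planning
study — per-patient anatomy effects shared by both arms, arm-specific
effects where the two optimization styles genuinely differ — directly in
histogram space.  Three DVH families are produced:

* targets: a truncated-normal main lobe just above the prescription
  (support >= 95% of the prescription, so V95% ~ 100 by construction) plus
  a tunable hot-spot lobe above 107% of the prescription whose weight is
  the fraction of volume in hot spots (so V107% tracks the configured
  weight);
* parallel organs (parotid-like): a low-dose bulk component plus a tunable
  high-dose tail above 40 Gy;
* serial organs (cord/stem-like): a truncated-normal whose upper support
  ends at a configurable shoulder dose, putting D1% within ~2 Gy of it.

Arms of the same patient share the anatomy draws and differ only through
arm parameters plus small independent arm noise, so paired differences
have a consistent sign wherever the configured arm effects are nonzero,
and are symmetric about zero when both arms use identical parameters.
Default arm parameters are set so that the default cohorts reproduce the
qualitative arm contrasts of biologically-optimized vs dose-volume
optimized head-and-neck plans (hot-spot burden up, parotid high-dose tail
down, serial organs unchanged); they target the published contrast
pattern, not any particular patient set.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import ndtr

from .dvh import DVH
from .io import PatientCase, Plan
from .metrics import ConformityInputs
from .radbio import FractionationScheme

__all__ = [
    "TargetArmParams",
    "SerialArmParams",
    "ParallelArmParams",
    "Variability",
    "GeneratorConfig",
    "synth_target_dvh",
    "synth_oar_dvh",
    "make_cohort",
]

ARM_BIO = "BBTP"   # biologically based planning arm
ARM_DV = "DVTP"    # dose/dose-volume based planning arm


# -- parameter blocks ----------------------------------------------------


@dataclass(frozen=True)
class TargetArmParams:
    """Target DVH shape for one arm.

    ``hot_weight`` is the volume fraction in the hot-spot lobe (centered at
    ``rx + hot_offset_gy``, supported above 1.07*rx); the main lobe sits at
    ``center_scale * rx`` with spread ``penumbra_gy``.
    """

    rx: float
    center_scale: float = 1.02
    penumbra_gy: float = 0.9
    hot_weight: float = 0.0
    hot_offset_gy: float = 5.5

    def __post_init__(self) -> None:
        if not self.rx > 0:
            raise ValueError("prescription must be positive")
        if self.hot_offset_gy < 0:
            raise ValueError("hot_offset_gy must be nonnegative")
        if not 0.0 <= self.hot_weight <= 1.0:
            raise ValueError("hot_weight must lie in [0, 1]")
        if not self.penumbra_gy > 0:
            raise ValueError("penumbra must be positive")


@dataclass(frozen=True)
class SerialArmParams:
    """Serial-organ DVH: truncated normal ending at the shoulder dose."""

    shoulder_gy: float
    rel_center: float = 0.80
    rel_sigma: float = 0.25

    def __post_init__(self) -> None:
        if not self.shoulder_gy > 0:
            raise ValueError("shoulder dose must be positive")
        if not (self.rel_sigma > 0 and 0 < self.rel_center < 1):
            raise ValueError("invalid serial shape parameters")


@dataclass(frozen=True)
class ParallelArmParams:
    """Parallel-organ DVH: low-dose bulk plus a high-dose tail."""

    bulk_center_gy: float
    tail_weight: float
    bulk_sigma_gy: float = 9.0
    bulk_max_gy: float = 40.0
    tail_center_gy: float = 50.0
    tail_sigma_gy: float = 5.0
    tail_max_gy: float = 72.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tail_weight <= 1.0:
            raise ValueError("tail_weight must lie in [0, 1]")
        if self.bulk_sigma_gy <= 0 or self.tail_sigma_gy <= 0:
            raise ValueError("spreads must be positive")


@dataclass(frozen=True)
class Variability:
    """Between-patient (shared across arms) and within-arm noise scales."""

    target_center_sd: float = 0.4        # Gy, shared
    target_center_arm_sd: float = 0.15   # Gy, per arm
    hot_weight_sd: float = 0.10          # fraction, shared
    hot_weight_arm_sd: float = 0.03      # fraction, per arm
    penumbra_logsd: float = 0.10         # shared log-scale factor
    serial_shoulder_sd: float = 1.5      # Gy, shared
    serial_shoulder_arm_sd: float = 0.8  # Gy, per arm
    parallel_center_sd: float = 3.0      # Gy, shared
    parallel_center_arm_sd: float = 1.2  # Gy, per arm
    tail_weight_sd: float = 0.03         # fraction, shared
    tail_weight_arm_sd: float = 0.015    # fraction, per arm
    conformity_sd: float = 0.02          # selectivity, shared
    conformity_arm_sd: float = 0.012     # selectivity, per arm
    volume_logsd: float = 0.15           # structure volume, shared


@dataclass
class GeneratorConfig:
    """Full description of one synthetic paired cohort."""

    stratum: str
    n_cases: int = 10
    seed: int = 0
    n_fractions: int = 35
    targets: dict[str, dict[str, TargetArmParams]] = field(default_factory=dict)
    serial: dict[str, dict[str, SerialArmParams]] = field(default_factory=dict)
    parallel: dict[str, dict[str, ParallelArmParams]] = field(default_factory=dict)
    variability: Variability = field(default_factory=Variability)
    abs_volume_cc: dict[str, float] = field(default_factory=dict)
    conformity_selectivity: float = 0.90
    bin_width: float = 0.1
    max_dose_gy: float = 85.0
    arms: tuple[str, str] = (ARM_BIO, ARM_DV)

    def __post_init__(self) -> None:
        if self.stratum not in {"early", "advanced"}:
            raise ValueError("stratum must be 'early' or 'advanced'")
        if self.n_cases < 1:
            raise ValueError("n_cases must be at least 1")

    # ---- canned configurations ----------------------------------------

    @classmethod
    def default(cls, stratum: str, n_cases: int = 10, seed: int = 0) -> "GeneratorConfig":
        """Arm contrasts matching the published early/advanced planning study."""
        if stratum == "early":
            targets = {
                "PTV70": {ARM_BIO: TargetArmParams(70.0, 1.020, 0.9, 0.15, 5.5),
                          ARM_DV: TargetArmParams(70.0, 1.020, 0.9, 0.00, 5.5)},
                "PTV60": {ARM_BIO: TargetArmParams(60.0, 1.083, 2.8, 0.10, 13.0),
                          ARM_DV: TargetArmParams(60.0, 1.112, 2.5, 0.02, 12.0)},
                "PTV54": {ARM_BIO: TargetArmParams(54.0, 1.077, 2.0, 0.00, 5.0),
                          ARM_DV: TargetArmParams(54.0, 1.046, 2.0, 0.00, 5.0)},
            }
            serial = {
                "brain_stem": _same_arms(SerialArmParams(48.2)),
                "spinal_cord": _same_arms(SerialArmParams(39.8)),
                "optic_nerve": _same_arms(SerialArmParams(14.5)),
                "optic_chiasma": _same_arms(SerialArmParams(13.0)),
                "eye_retina": {ARM_BIO: SerialArmParams(10.2),
                               ARM_DV: SerialArmParams(7.6)},
                "lens": {ARM_BIO: SerialArmParams(7.8),
                         ARM_DV: SerialArmParams(5.1)},
            }
            n_fractions = 35
        else:
            targets = {
                "PTV70": {ARM_BIO: TargetArmParams(70.0, 1.020, 0.9, 0.41, 5.5),
                          ARM_DV: TargetArmParams(70.0, 1.020, 0.9, 0.008, 5.5)},
                "PTV60": {ARM_BIO: TargetArmParams(60.0, 1.107, 2.8, 0.10, 13.0),
                          ARM_DV: TargetArmParams(60.0, 1.124, 2.5, 0.02, 12.0)},
                "PTV54": {ARM_BIO: TargetArmParams(54.0, 1.079, 2.0, 0.00, 5.0),
                          ARM_DV: TargetArmParams(54.0, 1.053, 2.0, 0.00, 5.0)},
            }
            serial = {
                "brain_stem": _same_arms(SerialArmParams(49.3)),
                "spinal_cord": _same_arms(SerialArmParams(39.5)),
                "optic_nerve": _same_arms(SerialArmParams(55.5)),
                "optic_chiasma": _same_arms(SerialArmParams(54.5)),
                "eye_retina": {ARM_BIO: SerialArmParams(24.9),
                               ARM_DV: SerialArmParams(13.4)},
                "lens": {ARM_BIO: SerialArmParams(21.2),
                         ARM_DV: SerialArmParams(7.4)},
            }
            n_fractions = 33
        parallel = {
            "parotid": {ARM_BIO: ParallelArmParams(29.5, 0.10),
                        ARM_DV: ParallelArmParams(26.0, 0.25)},
        }
        volumes = {"PTV70": 120.0, "PTV60": 250.0, "PTV54": 420.0,
                   "brain_stem": 28.0, "spinal_cord": 30.0,
                   "optic_nerve": 1.6, "optic_chiasma": 1.0,
                   "eye_retina": 2.4, "lens": 0.4, "parotid": 26.0}
        return cls(stratum=stratum, n_cases=n_cases, seed=seed,
                   n_fractions=n_fractions, targets=targets, serial=serial,
                   parallel=parallel, abs_volume_cc=volumes)

    @classmethod
    def null(cls, stratum: str = "early", n_cases: int = 10,
             seed: int = 0) -> "GeneratorConfig":
        """Both arms drawn from identical (dose-volume-arm) distributions."""
        cfg = cls.default(stratum, n_cases=n_cases, seed=seed)
        for block in (cfg.targets, cfg.serial, cfg.parallel):
            for structure, arms in block.items():
                ref = arms[ARM_DV]
                block[structure] = {a: copy.deepcopy(ref) for a in cfg.arms}
        return cfg


def _same_arms(p) -> dict:
    return {ARM_BIO: p, ARM_DV: copy.deepcopy(p)}


# -- histogram-space builders -------------------------------------------


def _grid(bin_width: float, max_dose: float) -> np.ndarray:
    n = int(round(max_dose / bin_width))
    return np.arange(n + 1, dtype=float) * bin_width


def _trunc_normal_mass(edges: np.ndarray, mu: float, sigma: float,
                       lo: float, hi: float) -> np.ndarray:
    """Per-bin mass of a normal(mu, sigma) truncated to [lo, hi]."""
    ce = np.clip(edges, lo, hi)
    z = ndtr((ce - mu) / sigma)
    mass = np.diff(z)
    total = mass.sum()
    if total < 1e-12:
        raise ValueError("truncated component carries no mass on the dose grid")
    return mass / total


def _mixture_dvh(name: str, edges: np.ndarray,
                 components: list[tuple[float, float, float, float, float]],
                 abs_volume_cc: Optional[float]) -> DVH:
    v = np.zeros(edges.size - 1)
    total_w = 0.0
    for w, mu, sigma, lo, hi in components:
        if w <= 0:
            continue
        v += w * _trunc_normal_mass(edges, mu, sigma, lo, hi)
        total_w += w
    if total_w <= 0:
        raise ValueError("mixture has no positive component weight")
    return DVH(name, edges, v / v.sum(), abs_volume_cc)


def synth_target_dvh(rx: float, penumbra: float, hot_weight: float,
                     hot_offset: float, rng: np.random.Generator, *,
                     center_scale: float = 1.02,
                     center_sd: float = 0.0, weight_sd: float = 0.0,
                     name: str = "PTV", bin_width: float = 0.1,
                     max_dose: float = 85.0,
                     abs_volume_cc: Optional[float] = None) -> DVH:
    """Target DVH: main lobe above 95% of rx plus a hot-spot lobe above 107%.

    ``center_sd``/``weight_sd`` add seeded jitter to the lobe center and the
    hot-spot weight; with the same generator state the output is
    bit-identical.
    """
    if hot_offset < 0:
        raise ValueError("hot_offset must be nonnegative")
    if not rx > 0:
        raise ValueError("rx must be positive")
    shift = rng.normal(0.0, center_sd) if center_sd > 0 else 0.0
    w = hot_weight + (rng.normal(0.0, weight_sd) if weight_sd > 0 else 0.0)
    w = float(np.clip(w, 0.0, 1.0))
    edges = _grid(bin_width, max_dose)
    lo_main = 0.95 * rx
    lo_hot = 1.07 * rx
    comps = [(1.0 - w, center_scale * rx + shift, penumbra, lo_main, max_dose)]
    if w > 0:
        comps.append((w, rx + hot_offset + shift, penumbra,
                      lo_hot, max_dose))
    return _mixture_dvh(name, edges, comps, abs_volume_cc)


def synth_oar_dvh(family: str, params, rng: np.random.Generator, *,
                  shift_sd: float = 0.0, tail_weight_sd: float = 0.0,
                  name: str = "OAR", bin_width: float = 0.1,
                  max_dose: float = 85.0,
                  abs_volume_cc: Optional[float] = None) -> DVH:
    """Organ-at-risk DVH of the 'serial' or 'parallel' family.

    Serial: truncated normal ending at the configured shoulder dose, so the
    produced D1% lands within ~2 Gy below the shoulder.  Parallel: low-dose
    bulk plus a tail above ``bulk_max_gy`` with the configured weight.
    """
    edges = _grid(bin_width, max_dose)
    shift = rng.normal(0.0, shift_sd) if shift_sd > 0 else 0.0
    if family == "serial":
        s = max(params.shoulder_gy + shift, 1.0)
        comps = [(1.0, params.rel_center * s, params.rel_sigma * s, 0.0, s)]
    elif family == "parallel":
        t = params.tail_weight + (rng.normal(0.0, tail_weight_sd)
                                  if tail_weight_sd > 0 else 0.0)
        t = float(np.clip(t, 0.0, 1.0))
        comps = [(1.0 - t, params.bulk_center_gy + shift, params.bulk_sigma_gy,
                  0.0, params.bulk_max_gy),
                 (t, params.tail_center_gy + shift, params.tail_sigma_gy,
                  params.bulk_max_gy, params.tail_max_gy)]
    else:
        raise ValueError(f"unknown OAR family {family!r}")
    return _mixture_dvh(name, edges, comps, abs_volume_cc)


# -- cohort assembly -----------------------------------------------------


def make_cohort(config: GeneratorConfig,
                rng: Optional[np.random.Generator] = None) -> list[PatientCase]:
    """Generate the paired cases described by a :class:`GeneratorConfig`.

    All randomness flows through one seeded generator (``config.seed``
    unless an explicit ``rng`` is passed); the two arms of a case share the
    per-patient anatomy draws and differ only through the configured arm
    parameters plus independent arm noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    var = config.variability
    fx = FractionationScheme(config.n_fractions)
    cases = []
    for i in range(config.n_cases):
        case_id = f"{config.stratum}-{i + 1:02d}"
        # ---- shared per-patient (anatomy) draws ----
        vol = {s: config.abs_volume_cc.get(s, 10.0)
               * float(np.exp(rng.normal(0.0, var.volume_logsd)))
               for s in (*config.targets, *config.serial, *config.parallel)}
        t_shift = {s: rng.normal(0.0, var.target_center_sd) for s in config.targets}
        t_wshift = {s: rng.normal(0.0, var.hot_weight_sd) for s in config.targets}
        t_pen = {s: float(np.exp(rng.normal(0.0, var.penumbra_logsd)))
                 for s in config.targets}
        s_shift = {s: rng.normal(0.0, var.serial_shoulder_sd) for s in config.serial}
        p_shift = {s: rng.normal(0.0, var.parallel_center_sd) for s in config.parallel}
        p_wshift = {s: rng.normal(0.0, var.tail_weight_sd) for s in config.parallel}
        c_shift = {s: rng.normal(0.0, var.conformity_sd) for s in config.targets}
        arms: dict[str, Plan] = {}
        for arm in config.arms:
            dvhs: dict[str, DVH] = {}
            conformity: dict[str, ConformityInputs] = {}
            for s, per_arm in config.targets.items():
                p = per_arm[arm]
                shift = t_shift[s] + rng.normal(0.0, var.target_center_arm_sd)
                w = np.clip(p.hot_weight + t_wshift[s]
                            + rng.normal(0.0, var.hot_weight_arm_sd), 0.0, 1.0)
                dvhs[s] = synth_target_dvh(
                    p.rx, p.penumbra_gy * t_pen[s], float(w), p.hot_offset_gy,
                    rng, center_scale=p.center_scale + shift / p.rx,
                    name=s, bin_width=config.bin_width,
                    max_dose=config.max_dose_gy, abs_volume_cc=vol[s])
                coverage = dvhs[s].volume_fraction_at_dose(p.rx)
                selectivity = float(np.clip(
                    config.conformity_selectivity + c_shift[s]
                    + rng.normal(0.0, var.conformity_arm_sd), 0.5, 0.999))
                v_t_ref = coverage * vol[s]
                if v_t_ref > 0:
                    conformity[s] = ConformityInputs(
                        v_t_ref=v_t_ref, v_t=vol[s], v_ref=v_t_ref / selectivity)
            for s, per_arm in config.serial.items():
                p = per_arm[arm]
                shift = s_shift[s] + rng.normal(0.0, var.serial_shoulder_arm_sd)
                dvhs[s] = synth_oar_dvh(
                    "serial", replace(p, shoulder_gy=max(p.shoulder_gy + shift, 1.0)),
                    rng, name=s, bin_width=config.bin_width,
                    max_dose=config.max_dose_gy, abs_volume_cc=vol[s])
            for s, per_arm in config.parallel.items():
                p = per_arm[arm]
                shift = p_shift[s] + rng.normal(0.0, var.parallel_center_arm_sd)
                t = np.clip(p.tail_weight + p_wshift[s]
                            + rng.normal(0.0, var.tail_weight_arm_sd), 0.0, 1.0)
                dvhs[s] = synth_oar_dvh(
                    "parallel",
                    replace(p, bulk_center_gy=p.bulk_center_gy + shift,
                            tail_weight=float(t)),
                    rng, name=s, bin_width=config.bin_width,
                    max_dose=config.max_dose_gy, abs_volume_cc=vol[s])
            arms[arm] = Plan(plan_id=f"{case_id}-{arm}", arm=arm, fractions=fx,
                             dvhs=dvhs, conformity=conformity)
        tcp_row = None
        if config.stratum == "advanced":
            tcp_row = "t3" if i < (config.n_cases + 1) // 2 else "stage4"
        cases.append(PatientCase(case_id=case_id, stage_stratum=config.stratum,
                                 arms=arms, tcp_row=tcp_row))
    return cases
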