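"""Constraint-satisfaction evaluation for organ-at-risk acceptability rules.

Two layers: simple predicates mirroring the optimizer's constraint taxonomy
(Min/Max dose, Min/Max DVH, EUD bounds, dose uniformity, mean dose), and
OR-style clinical acceptability rules with a primary dose limit plus
fallback branches that rescue the rule when the primary cannot be achieved
(e.g. parotid: mean <= 26 Gy, or else < 50% of the volume above 30 Gy).

"Maximum dose" here is the true top of the occupied DVH range (D at
cumulative volume 0), not the D2% proxy used for target reporting.
The dose-uniformity constraint interprets its "std.dev %" threshold as the
coefficient of variation of dose within the structure, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from .dvh import DVH
from .radbio import geud

__all__ = [
    "ConstraintSpec",
    "ConstraintResult",
    "AcceptabilityReport",
    "evaluate_constraint",
    "plan_acceptability",
    "load_ruleset",
    "default_ruleset",
]

_SIMPLE_KINDS = {
    "MinDose", "MaxDose", "MinDVH", "MaxDVH", "MinEUD", "MaxEUD",
    "TargetEUD", "Uniformity", "MeanDose",
}
_OR_KINDS = {"MaxDoseOrDVH", "MeanDoseOrDVH"}
#: optimizer-only construct: representable, never evaluated
_OPTIMIZER_ONLY = {"TargetConformance"}
_TOL = 1e-9


@dataclass(frozen=True)
class ConstraintSpec:
    """One acceptability constraint.

    ``kind`` is one of the simple kinds (MinDose, MaxDose, MinDVH, MaxDVH,
    MinEUD, MaxEUD, TargetEUD, Uniformity, MeanDose), an OR-kind
    (MaxDoseOrDVH, MeanDoseOrDVH) whose ``fallback`` lists the rescue
    branches, or TargetConformance (parsed but rejected at evaluation: it
    constrains the optimizer's spatial dose falloff, which a DVH cannot
    measure).  Volumes are percent of structure volume; ``volume_cc`` gives
    the "hottest 1 cc" style variants and requires an absolute volume on
    the DVH.  ``strict`` turns <= into < for the comparison.
    """

    kind: str
    dose_gy: Optional[float] = None
    volume_pct: Optional[float] = None
    volume_cc: Optional[float] = None
    a_param: Optional[float] = None
    stddev_pct: Optional[float] = None
    strict: bool = False
    target_eud_tol_gy: float = 0.5
    fallback: tuple["ConstraintSpec", ...] = ()
    name: str = ""
    structures: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _SIMPLE_KINDS | _OR_KINDS | _OPTIMIZER_ONLY:
            raise ValueError(f"unknown constraint kind {self.kind!r}")
        needs_dose = self.kind not in {"Uniformity", "TargetConformance"}
        if needs_dose and self.dose_gy is None:
            raise ValueError(f"{self.kind} requires dose_gy")
        if self.kind in {"MinDVH", "MaxDVH"}:
            if self.volume_pct is None and self.volume_cc is None:
                raise ValueError(f"{self.kind} requires volume_pct or volume_cc")
            if self.volume_pct is not None and not 0 < self.volume_pct <= 100:
                raise ValueError("volume_pct must lie in (0, 100]")
        if self.kind in {"MinEUD", "MaxEUD", "TargetEUD"} and self.a_param is None:
            raise ValueError(f"{self.kind} requires a_param")
        if self.kind == "Uniformity" and self.stddev_pct is None:
            raise ValueError("Uniformity requires stddev_pct")
        if self.kind in _OR_KINDS and not self.fallback:
            raise ValueError(f"{self.kind} requires at least one fallback branch")

    @classmethod
    def from_mapping(cls, raw: dict) -> "ConstraintSpec":
        raw = dict(raw)
        fallback = tuple(cls.from_mapping(f) for f in raw.pop("fallback", []))
        structures = tuple(raw.pop("structures", ()))
        return cls(fallback=fallback, structures=structures, **raw)


@dataclass(frozen=True)
class ConstraintResult:
    """Outcome of evaluating one constraint against one structure's DVH."""

    structure: str
    spec: ConstraintSpec
    met: bool
    branch: Optional[str]  # "primary" | "fallback" | None (unevaluated)
    measured: dict[str, float] = field(default_factory=dict)


def _cmp_le(value: float, limit: float, strict: bool) -> bool:
    return value < limit if strict else value <= limit + _TOL


def _cmp_ge(value: float, limit: float, strict: bool) -> bool:
    return value > limit if strict else value >= limit - _TOL


def _eval_simple(dvh: DVH, spec: ConstraintSpec) -> tuple[bool, dict[str, float]]:
    kind = spec.kind
    if kind == "MinDose":
        v = dvh.min_dose()
        return _cmp_ge(v, spec.dose_gy, spec.strict), {"min_dose_gy": v}
    if kind == "MaxDose":
        v = dvh.max_dose()
        return _cmp_le(v, spec.dose_gy, spec.strict), {"max_dose_gy": v}
    if kind == "MeanDose":
        v = dvh.mean_dose()
        return _cmp_le(v, spec.dose_gy, spec.strict), {"mean_dose_gy": v}
    if kind in {"MinDVH", "MaxDVH"}:
        if spec.volume_cc is not None:
            # dose to the hottest volume_cc; errors without absolute volume
            v = dvh.dose_to_cc(spec.volume_cc)
            key = f"d_{spec.volume_cc:g}cc_gy"
        else:
            v = dvh.dose_at_volume_fraction(spec.volume_pct / 100.0)
            key = f"d{spec.volume_pct:g}pct_gy"
        if kind == "MaxDVH":
            # no more than volume_pct (or cc) may receive >= dose_gy
            return _cmp_le(v, spec.dose_gy, spec.strict), {key: v}
        return _cmp_ge(v, spec.dose_gy, spec.strict), {key: v}
    if kind in {"MinEUD", "MaxEUD", "TargetEUD"}:
        v = geud(dvh, spec.a_param)
        m = {"eud_gy": v}
        if kind == "MinEUD":
            return _cmp_ge(v, spec.dose_gy, spec.strict), m
        if kind == "MaxEUD":
            return _cmp_le(v, spec.dose_gy, spec.strict), m
        return abs(v - spec.dose_gy) <= spec.target_eud_tol_gy, m
    if kind == "Uniformity":
        mean = dvh.mean_dose()
        if mean <= 0:
            raise ValueError("uniformity undefined for zero mean dose")
        cov = 100.0 * dvh.std_dose() / mean
        return _cmp_le(cov, spec.stddev_pct, spec.strict), {"dose_cov_pct": cov}
    raise AssertionError(kind)


def evaluate_constraint(dvh: DVH, spec: ConstraintSpec,
                        structure: Optional[str] = None) -> ConstraintResult:
    """Evaluate one constraint, reporting which branch satisfied it."""
    structure = structure or dvh.structure_name
    if spec.kind in _OPTIMIZER_ONLY:
        raise ValueError(
            f"{spec.kind} is an optimizer-only construct and cannot be "
            "evaluated from a DVH")
    if spec.kind in _SIMPLE_KINDS:
        met, measured = _eval_simple(dvh, spec)
        return ConstraintResult(structure, spec, met, "primary" if met else None,
                                measured)
    # OR-kinds: primary limit, rescued by any satisfied fallback branch
    primary_kind = "MaxDose" if spec.kind == "MaxDoseOrDVH" else "MeanDose"
    primary = ConstraintSpec(kind=primary_kind, dose_gy=spec.dose_gy,
                             strict=spec.strict)
    met, measured = _eval_simple(dvh, primary)
    if met:
        return ConstraintResult(structure, spec, True, "primary", measured)
    for fb in spec.fallback:
        fb_met, fb_measured = _eval_simple(dvh, fb)
        measured.update(fb_measured)
        if fb_met:
            return ConstraintResult(structure, spec, True, "fallback", measured)
    return ConstraintResult(structure, spec, False, None, measured)


@dataclass
class AcceptabilityReport:
    """Aggregated constraint outcomes for one plan."""

    results: list[ConstraintResult]
    unevaluated: list[tuple[str, str]]  # (rule name, structure) pairs

    @property
    def passed(self) -> bool:
        return not self.unevaluated and all(r.met for r in self.results)

    def to_rows(self) -> list[dict]:
        rows = [
            {"rule": r.spec.name, "structure": r.structure, "kind": r.spec.kind,
             "met": r.met, "branch": r.branch or "",
             **{k: round(v, 6) for k, v in r.measured.items()}}
            for r in self.results
        ]
        rows += [{"rule": name, "structure": s, "kind": "", "met": False,
                  "branch": "unevaluated"} for name, s in self.unevaluated]
        return rows


def plan_acceptability(dvhs: dict[str, DVH],
                       ruleset: Sequence[ConstraintSpec]) -> AcceptabilityReport:
    """Check every rule of a ruleset against the plan's structure DVHs.

    A rule applies to every structure it names; structures missing from the
    plan are listed as unevaluated and fail the plan overall.
    """
    results: list[ConstraintResult] = []
    unevaluated: list[tuple[str, str]] = []
    for spec in ruleset:
        targets = spec.structures or (spec.name,)
        for s in targets:
            if s in dvhs:
                results.append(evaluate_constraint(dvhs[s], spec, structure=s))
            else:
                unevaluated.append((spec.name or spec.kind, s))
    return AcceptabilityReport(results, unevaluated)


def load_ruleset(path) -> list[ConstraintSpec]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [ConstraintSpec.from_mapping(r) for r in raw["rules"]]


def default_ruleset() -> list[ConstraintSpec]:
    """The packaged clinical OAR acceptability rules (6 OAR classes)."""
    from importlib.resources import files

    raw = yaml.safe_load(files("planbio.data").joinpath("oar_constraints.yaml").read_text())
    return [ConstraintSpec.from_mapping(r) for r in raw["rules"]]
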