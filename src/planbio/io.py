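"""Tabular I/O: the DVH CSV dialect and plan / cohort YAML manifests.

DVH files carry one structure each::

    # structure=<name> kind=<cumulative|differential> abs_volume_cc=<float|NA>
    dose_gy,volume
    ...

with one row per bin edge.  For differential files the volume column holds
the fraction in the bin starting at that edge (last row 0); for cumulative
files it holds the fraction receiving at least that dose.  Floats are
written with ``repr`` so a write/read/write cycle is bit-exact.

A *plan* is a directory of DVH files plus a ``plan.yaml`` manifest (plan
id, arm label, fraction count, structure-to-file map, optional conformity
volumes per target).  A *cohort* is a ``cohort.yaml`` listing paired cases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dvh import DVH
from .metrics import ConformityInputs
from .radbio import FractionationScheme

__all__ = [
    "Plan",
    "PatientCase",
    "read_dvh_csv",
    "write_dvh_csv",
    "read_plan",
    "write_plan",
    "read_cohort",
    "write_cohort",
]


@dataclass
class Plan:
    """One treatment plan: per-structure DVHs plus fractionation metadata."""

    plan_id: str
    arm: str  # e.g. "BBTP" or "DVTP"
    fractions: FractionationScheme
    dvhs: dict[str, DVH]
    conformity: dict[str, ConformityInputs] = field(default_factory=dict)


@dataclass
class PatientCase:
    """Paired plans (two arms) for one patient.

    ``stage_stratum`` is 'early' or 'advanced'; advanced cases additionally
    carry ``tcp_row`` ('t3' or 'stage4') naming the staged TCP parameter row.
    """

    case_id: str
    stage_stratum: str
    arms: dict[str, Plan]
    tcp_row: Optional[str] = None

    def __post_init__(self) -> None:
        if self.stage_stratum not in {"early", "advanced"}:
            raise ValueError("stage_stratum must be 'early' or 'advanced'")
        if len(self.arms) != 2:
            raise ValueError("a patient case needs exactly two arms")
        sets = [frozenset(p.dvhs) for p in self.arms.values()]
        if sets[0] != sets[1]:
            raise ValueError("both arms must carry the same structure set")
        if self.stage_stratum == "advanced" and self.tcp_row not in {"t3", "stage4"}:
            raise ValueError("advanced cases need tcp_row 't3' or 'stage4'")

    @property
    def tcp_stage_key(self) -> str:
        return "early" if self.stage_stratum == "early" else self.tcp_row


# -- DVH CSV ------------------------------------------------------------


def write_dvh_csv(dvh: DVH, path) -> None:
    av = "NA" if dvh.abs_volume_cc is None else repr(float(dvh.abs_volume_cc))
    lines = [f"# structure={dvh.structure_name} kind={dvh.kind} abs_volume_cc={av}",
             "dose_gy,volume"]
    if dvh.kind == "differential":
        vols = np.concatenate([dvh.volume, [0.0]])
    else:
        vols = dvh.volume
    for e, v in zip(dvh.bin_edges, vols):
        lines.append(f"{float(e)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_dvh_csv(path) -> DVH:
    text = Path(path).read_text().strip().splitlines()
    if not text or not text[0].startswith("#"):
        raise ValueError(f"{path}: missing DVH header line")
    header = dict(tok.split("=", 1) for tok in text[0].lstrip("# ").split())
    try:
        name, kind, av = header["structure"], header["kind"], header["abs_volume_cc"]
    except KeyError as exc:
        raise ValueError(f"{path}: malformed DVH header") from exc
    if text[1].strip() != "dose_gy,volume":
        raise ValueError(f"{path}: expected 'dose_gy,volume' column line")
    rows = [ln.split(",") for ln in text[2:] if ln.strip()]
    edges = np.array([float(r[0]) for r in rows])
    vols = np.array([float(r[1]) for r in rows])
    abs_cc = None if av == "NA" else float(av)
    if kind == "differential":
        if abs(vols[-1]) > 1e-12:
            raise ValueError(f"{path}: differential file must end with a zero row")
        return DVH(name, edges, vols[:-1], abs_cc, "differential")
    return DVH(name, edges, vols, abs_cc, "cumulative")


# -- plan manifests ------------------------------------------------------


def write_plan(plan: Plan, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    structures = {}
    for name, dvh in sorted(plan.dvhs.items()):
        fname = f"{name}.csv"
        write_dvh_csv(dvh, directory / fname)
        structures[name] = fname
    manifest = {
        "plan_id": plan.plan_id,
        "arm": plan.arm,
        "fractions": plan.fractions.n_fractions,
        "structures": structures,
        "conformity": {
            s: {"v_t_ref": float(c.v_t_ref), "v_t": float(c.v_t),
                "v_ref": float(c.v_ref)}
            for s, c in sorted(plan.conformity.items())
        },
    }
    with open(directory / "plan.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return directory / "plan.yaml"


def read_plan(directory) -> Plan:
    directory = Path(directory)
    manifest_path = directory / "plan.yaml"
    try:
        with open(manifest_path) as fh:
            m = yaml.safe_load(fh)
        dvhs = {name: read_dvh_csv(directory / fname)
                for name, fname in m["structures"].items()}
        conformity = {s: ConformityInputs(**c)
                      for s, c in (m.get("conformity") or {}).items()}
        return Plan(plan_id=str(m["plan_id"]), arm=str(m["arm"]),
                    fractions=FractionationScheme(int(m["fractions"])),
                    dvhs=dvhs, conformity=conformity)
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ValueError(f"malformed plan manifest {manifest_path}: {exc}") from exc


# -- cohort manifests ----------------------------------------------------


def write_cohort(cases: list[PatientCase], directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for case in cases:
        arms = {}
        for arm, plan in sorted(case.arms.items()):
            rel = os.path.join(case.case_id, arm)
            write_plan(plan, directory / rel)
            arms[arm] = rel
        entries.append({"case_id": case.case_id,
                        "stage_stratum": case.stage_stratum,
                        "tcp_row": case.tcp_row, "arms": arms})
    with open(directory / "cohort.yaml", "w") as fh:
        yaml.safe_dump({"cases": entries}, fh, sort_keys=True)
    return directory / "cohort.yaml"


def read_cohort(path) -> list[PatientCase]:
    path = Path(path)
    if path.is_dir():
        path = path / "cohort.yaml"
    base = path.parent
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cases = []
        for entry in raw["cases"]:
            arms = {arm: read_plan(base / rel)
                    for arm, rel in entry["arms"].items()}
            cases.append(PatientCase(case_id=str(entry["case_id"]),
                                     stage_stratum=entry["stage_stratum"],
                                     arms=arms, tcp_row=entry.get("tcp_row")))
        return cases
    except (KeyError, TypeError, yaml.YAMLError) as exc:
        raise ValueError(f"malformed cohort manifest {path}: {exc}") from exc
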