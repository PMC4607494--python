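"""Subject-level records, HLA-B27 carrier classification, tabulation and I/O.

The analysis works on two binary carrier factors per subject: HLA-B27
carriership, tagged by the rs13202464 genotype (GG/AG carry, AA does not),
and directly assayed HLA-B60 carriership. Subjects are cross-classified
into four strata; the central object is the 2x2x2 case/control x B27 x B60
integer count table (:class:`JointTable`).

Stratum ordering is fixed everywhere as
(B27+,B60+), (B27+,B60-), (B27-,B60+), (B27-,B60-), the doubly-negative
stratum being the reference (last).
"""

from __future__ import annotations

import enum
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: fixed stratum order, reference last
STRATUM_LABELS: tuple[str, ...] = ("B27+/B60+", "B27+/B60-", "B27-/B60+", "B27-/B60-")

#: mandatory subject CSV columns
REQUIRED_COLUMNS = ("subject_id", "status", "rs13202464", "hla_b60")
OPTIONAL_COLUMNS = ("basdai", "basfi", "basg")


class Status(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Genotype(str, enum.Enum):
    AA = "AA"
    AG = "AG"
    GG = "GG"
    MISSING = "missing"


class Carrier(str, enum.Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    MISSING = "missing"


def classify_b27(genotype: Genotype | str) -> Carrier:
    """Classify a rs13202464 genotype into HLA-B27 carrier status.

    GG and AG genotypes tag B27 carriership; AA tags non-carriership.
    A missing genotype yields :attr:`Carrier.MISSING`, the explicit signal
    that the record cannot be tabulated.
    """
    genotype = Genotype(genotype)
    if genotype is Genotype.MISSING:
        return Carrier.MISSING
    if genotype in (Genotype.GG, Genotype.AG):
        return Carrier.CARRIER
    return Carrier.NONCARRIER


@dataclass(frozen=True)
class SubjectRecord:
    """One genotyped individual.

    Severity scores (BASDAI/BASFI/BAS-G) are 0-10 continuous instrument
    scores and are optional; they are only collected for cases in the
    study design this package models.
    """

    subject_id: str
    status: Status
    rs13202464: Genotype = Genotype.MISSING
    b60: Carrier = Carrier.MISSING
    basdai: float | None = None
    basfi: float | None = None
    basg: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "status", Status(self.status))
        object.__setattr__(self, "rs13202464", Genotype(self.rs13202464))
        object.__setattr__(self, "b60", Carrier(self.b60))
        for name in ("basdai", "basfi", "basg"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= float(v) <= 10.0):
                raise ValueError(f"{name}={v!r} outside the 0-10 instrument scale")

    @property
    def b27(self) -> Carrier:
        return classify_b27(self.rs13202464)

    @property
    def stratum(self) -> int | None:
        """Index into :data:`STRATUM_LABELS`, or None if any factor missing."""
        b27, b60 = self.b27, self.b60
        if Carrier.MISSING in (b27, b60):
            return None
        i = 0 if b27 is Carrier.CARRIER else 1
        j = 0 if b60 is Carrier.CARRIER else 1
        return 2 * i + j


@dataclass(frozen=True)
class MarginalSummary:
    """Arm totals and per-factor carrier counts (the printed margins)."""

    n_cases: int
    n_controls: int
    cases_b27pos: int
    cases_b60pos: int
    controls_b27pos: int
    controls_b60pos: int

    def __post_init__(self) -> None:
        for arm, total in (("cases", self.n_cases), ("controls", self.n_controls)):
            if total <= 0:
                raise ValueError(f"{arm} total must be positive")
        if not (0 <= self.cases_b27pos <= self.n_cases
                and 0 <= self.cases_b60pos <= self.n_cases):
            raise ValueError("case carrier counts exceed the case-arm total")
        if not (0 <= self.controls_b27pos <= self.n_controls
                and 0 <= self.controls_b60pos <= self.n_controls):
            raise ValueError("control carrier counts exceed the control-arm total")


@dataclass(frozen=True)
class TaggingConstants:
    """Documented tag-SNP performance of rs13202464 for HLA-B27.

    Carried as metadata only; never recomputed by this package.
    """

    sensitivity: float = 0.987
    specificity: float = 0.980

    def __post_init__(self) -> None:
        if not (0 < self.sensitivity <= 1 and 0 < self.specificity <= 1):
            raise ValueError("sensitivity/specificity must lie in (0, 1]")


@dataclass(frozen=True)
class JointTable:
    """2x2x2 case/control x B27 x B60 count table.

    ``case_counts`` and ``control_counts`` are 2x2 integer arrays with
    axis 0 = B27 (index 0 carrier, 1 non-carrier) and axis 1 = B60
    likewise, so the row-major flattening follows the fixed stratum order.
    """

    case_counts: np.ndarray
    control_counts: np.ndarray
    factor_labels: tuple[str, str] = ("HLA-B27", "HLA-B60")

    def __post_init__(self) -> None:
        for name in ("case_counts", "control_counts"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (2, 2):
                raise ValueError(f"{name} must be 2x2, got {arr.shape}")
            if not np.all(arr == np.floor(arr)) or np.any(arr < 0):
                raise ValueError(f"{name} must hold non-negative integers")
            arr = arr.astype(np.int64)
            arr.setflags(write=False)
            object.__setattr__(self, name, arr)

    # -- flattened views in fixed stratum order ------------------------------
    @property
    def cases(self) -> np.ndarray:
        """Case counts (a11, a10, a01, a00) in fixed stratum order."""
        return self.case_counts.ravel()

    @property
    def controls(self) -> np.ndarray:
        return self.control_counts.ravel()

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())

    def stratum_2x2(self, stratum: int) -> tuple[int, int, int, int]:
        """2x2 (stratum cases, reference cases, stratum controls, reference
        controls) comparing ``stratum`` against the doubly-negative reference."""
        if stratum not in (0, 1, 2):
            raise ValueError("stratum must be 0 (B27+/B60+), 1 (B27+/B60-) or 2 (B27-/B60+)")
        a, b = self.cases, self.controls
        return int(a[stratum]), int(a[3]), int(b[stratum]), int(b[3])

    def marginals(self) -> MarginalSummary:
        a, b = self.cases, self.controls
        return MarginalSummary(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            cases_b27pos=int(a[0] + a[1]),
            cases_b60pos=int(a[0] + a[2]),
            controls_b27pos=int(b[0] + b[1]),
            controls_b60pos=int(b[0] + b[2]),
        )

    def swap_factors(self) -> "JointTable":
        """Relabel the two factors (transpose both 2x2 arms)."""
        return JointTable(self.case_counts.T.copy(), self.control_counts.T.copy(),
                          (self.factor_labels[1], self.factor_labels[0]))

    def scale(self, k: int) -> "JointTable":
        return JointTable(self.case_counts * k, self.control_counts * k, self.factor_labels)

    # -- JSON round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cases": self.case_counts.tolist(),
            "controls": self.control_counts.tolist(),
            "factor_labels": list(self.factor_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointTable":
        for key in ("cases", "controls"):
            if key not in d:
                raise ValueError(f"count-table JSON missing key {key!r}")
            arr = np.asarray(d[key])
            if arr.dtype.kind not in "iu":
                if not np.all(arr == np.floor(arr)):
                    raise ValueError(f"non-integer counts under {key!r}")
        labels = tuple(d.get("factor_labels", ("HLA-B27", "HLA-B60")))
        return cls(np.asarray(d["cases"]), np.asarray(d["controls"]), labels)


def tabulate(records: Iterable[SubjectRecord], *, return_excluded: bool = False):
    """Cross-classify subjects into the 2x2x2 joint table.

    Records with a missing genotype or B60 flag are excluded listwise and
    the exclusion count is logged. Raises on empty input or an empty
    case/control arm.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot tabulate an empty record collection")
    cases = np.zeros(4, dtype=np.int64)
    controls = np.zeros(4, dtype=np.int64)
    excluded = 0
    for rec in records:
        s = rec.stratum
        if s is None:
            excluded += 1
            continue
        (cases if rec.status is Status.CASE else controls)[s] += 1
    if excluded:
        logger.info("tabulate: excluded %d record(s) with missing genotype/carrier data", excluded)
    for name, arm in (("case", cases), ("control", controls)):
        if arm.sum() == 0:
            raise ValueError(f"empty {name} arm: no complete records with status={name}")
    table = JointTable(cases.reshape(2, 2), controls.reshape(2, 2))
    if return_excluded:
        return table, excluded
    return table


def _parse_score(value, row: int, name: str) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row}: {name}={value!r} is not a number") from None
    return v


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Read subject records from CSV.

    Requires the documented header (subject_id, status, rs13202464,
    hla_b60 [+ basdai, basfi, basg]); unknown columns are ignored with a
    warning; malformed tokens are rejected with their row number
    (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"subject CSV missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown column(s): {', '.join(unknown)}", stacklevel=2)

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        status_tok = str(getattr(row, "status")).strip().lower()
        if status_tok not in ("case", "control"):
            raise ValueError(f"row {i}: status {getattr(row, 'status')!r} is not case/control")
        geno_tok = str(getattr(row, "rs13202464")).strip()
        if geno_tok == "":
            geno_tok = "missing"
        try:
            geno = Genotype(geno_tok)
        except ValueError:
            raise ValueError(f"row {i}: rs13202464 genotype {geno_tok!r} is not AA/AG/GG") from None
        b60_tok = str(getattr(row, "hla_b60")).strip().lower()
        if b60_tok == "":
            b60_tok = "missing"
        try:
            b60 = Carrier(b60_tok)
        except ValueError:
            raise ValueError(f"row {i}: hla_b60 {b60_tok!r} is not carrier/noncarrier") from None
        scores = {name: _parse_score(getattr(row, name, None), i, name)
                  for name in OPTIONAL_COLUMNS if name in df.columns}
        records.append(SubjectRecord(str(getattr(row, "subject_id")), Status(status_tok),
                                     geno, b60, **scores))
    return records


def write_subjects(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records to the documented CSV layout."""
    rows = []
    for r in records:
        rows.append({
            "subject_id": r.subject_id,
            "status": r.status.value,
            "rs13202464": "" if r.rs13202464 is Genotype.MISSING else r.rs13202464.value,
            "hla_b60": "" if r.b60 is Carrier.MISSING else r.b60.value,
            "basdai": "" if r.basdai is None else f"{r.basdai:.3f}",
            "basfi": "" if r.basfi is None else f"{r.basfi:.3f}",
            "basg": "" if r.basg is None else f"{r.basg:.3f}",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_table(table: JointTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(table.to_dict(), indent=1) + "\n")


def read_table(path: str | Path) -> JointTable:
    return JointTable.from_dict(json.loads(Path(path).read_text()))
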