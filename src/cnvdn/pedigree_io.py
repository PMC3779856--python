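"""Pedigree and measurement file handling.

Input formats
-------------
Pedigree files use a PED-like dialect: whitespace-delimited columns

    FID IID FATHER MOTHER SEX PHENO [COVAR1 COVAR2 ...]

with ``0`` marking a missing parent.  The phenotype column is interpreted
with the standard PED convention (2 = affected, 1 = unaffected, 0/-9 =
missing) by default; ``phenotype_coding="binary"`` switches to 1/0 coding
with -9/NA missing.

Measurements are long-format (tidy) tables with one row per replicate:

    IID  MARKER  REP  VALUE

where VALUE is the real-valued quantitative copy number produced upstream
(e.g. by qPCR dCt quantification).  The long format supports ragged
replicate counts per individual (two-stage designs yield 2 or 6
replicates) without padding.

Only two-generation (nuclear) families are accepted: every named parent
must itself be a founder of the same family.  Deeper pedigrees are
rejected with an error naming the offending family rather than silently
split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .results import AssociationFit, PosteriorSummary

log = logging.getLogger("cnvdn")

MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structural problem in a pedigree or measurement file."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``affected`` is 1/0/None (None = missing phenotype); ``covariates``
    is a possibly empty tuple of real-valued covariates in file order.
    """

    family_id: str
    individual_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int | None = None
    affected: int | None = None
    covariates: tuple[float, ...] = ()

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Family:
    """A nuclear family: founder (parental) generation plus offspring."""

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    @property
    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    @property
    def offspring(self) -> list[Individual]:
        return [m for m in self.members.values() if not m.is_founder]

    def parents_of(self, iid: str) -> tuple[str | None, str | None]:
        m = self.members[iid]
        return m.father_id, m.mother_id


@dataclass
class Pedigree:
    """A collection of validated nuclear families."""

    families: dict[str, Family] = field(default_factory=dict)

    def __len__(self) -> int:
        return sum(len(f.members) for f in self.families.values())

    def __iter__(self) -> Iterable[Family]:
        return iter(self.families.values())

    @property
    def individuals(self) -> dict[str, Individual]:
        out: dict[str, Individual] = {}
        for fam in self.families.values():
            out.update(fam.members)
        return out

    def structure_summary(self) -> pd.DataFrame:
        """Cross-tabulate families by (number of parents, number of children).

        Families containing at least one parent link count their founders
        as parents and non-founders as children.  Families with no
        internal parent links are read as sibships of children whose
        parents were not recruited (0 parents, all members children).
        """
        rows = []
        for fam in self.families.values():
            n_off = len(fam.offspring)
            if n_off == 0:
                rows.append((0, len(fam.members)))
            else:
                rows.append((len(fam.founders), n_off))
        df = pd.DataFrame(rows, columns=["n_parents", "n_children"])
        return pd.crosstab(df["n_parents"], df["n_children"], margins=True)


@dataclass
class MeasurementSet:
    """Replicated quantitative CN measurements, one row per replicate.

    ``data`` columns: individual_id, marker_id, replicate, value.
    Values are finite reals; they may fall outside the plausible copy
    number range and are never clipped here.
    """

    data: pd.DataFrame

    @property
    def markers(self) -> list[str]:
        return sorted(self.data["marker_id"].unique())

    def replicate_counts(self) -> pd.Series:
        """n_ij per (individual, marker)."""
        if self.data.empty:
            return pd.Series(dtype=int)
        return self.data.groupby(["individual_id", "marker_id"]).size()

    def replicates(self, individual_id: str, marker_id: str) -> np.ndarray:
        sel = self.data[
            (self.data["individual_id"] == individual_id)
            & (self.data["marker_id"] == marker_id)
        ]
        return sel["value"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers


def _decode_phenotype(raw: str, coding: str) -> int | None:
    try:
        v = float(raw)
    except ValueError:
        return None
    if coding == "ped":
        if v == 2:
            return 1
        if v == 1:
            return 0
        return None
    if coding == "binary":
        if v == 1:
            return 1
        if v == 0:
            return 0
        return None
    raise ValueError(f"unknown phenotype coding {coding!r}")


def read_pedigree(path: str | Path, phenotype_coding: str = "ped") -> Pedigree:
    """Read and validate a PED-like pedigree file.

    Raises :class:`PedigreeError` for duplicate individual IDs, parent
    links to unknown individuals, or families deeper than two
    generations.  Logs a family-structure summary on success.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(
                    f"{path}:{lineno}: expected at least 6 columns, got {len(fields)}"
                )
            rows.append(fields)

    ped = Pedigree()
    seen: set[str] = set()
    for fields in rows:
        fid, iid, fat, mot, sex, pheno = fields[:6]
        if iid in seen:
            raise PedigreeError(f"duplicate individual ID {iid!r}")
        seen.add(iid)
        try:
            covs = tuple(float(c) for c in fields[6:])
        except ValueError as exc:
            raise PedigreeError(f"non-numeric covariate for {iid!r}: {exc}") from exc
        ind = Individual(
            family_id=fid,
            individual_id=iid,
            father_id=None if fat == MISSING_PARENT else fat,
            mother_id=None if mot == MISSING_PARENT else mot,
            sex=int(sex) if sex in {"1", "2"} else None,
            affected=_decode_phenotype(pheno, phenotype_coding),
            covariates=covs,
        )
        ped.families.setdefault(fid, Family(family_id=fid)).members[iid] = ind

    _validate_pedigree(ped)
    summary = ped.structure_summary()
    log.info(
        "read %d families / %d individuals from %s\nfamily structure "
        "(#parents x #children):\n%s",
        len(ped.families),
        len(ped),
        path,
        summary.to_string(),
    )
    return ped


def _validate_pedigree(ped: Pedigree) -> None:
    for fam in ped.families.values():
        for ind in fam.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is None:
                    continue
                if pid not in fam.members:
                    raise PedigreeError(
                        f"individual {ind.individual_id!r} in family "
                        f"{fam.family_id!r} links to unknown parent {pid!r}"
                    )
                parent = fam.members[pid]
                if not parent.is_founder:
                    raise PedigreeError(
                        f"family {fam.family_id!r} spans more than two "
                        f"generations: parent {pid!r} of "
                        f"{ind.individual_id!r} has parents of its own; "
                        "only nuclear families are supported"
                    )


_MEAS_COLUMNS = ["individual_id", "marker_id", "replicate", "value"]
_HEADER_ALIASES = {
    "iid": "individual_id",
    "individual": "individual_id",
    "individual_id": "individual_id",
    "marker": "marker_id",
    "marker_id": "marker_id",
    "rep": "replicate",
    "replicate": "replicate",
    "value": "value",
    "cn": "value",
}


def read_measurements(path: str | Path, pedigree: Pedigree) -> MeasurementSet:
    """Read a long-format measurement table and resolve IDs against a pedigree.

    A header row is optional; headerless files must have exactly the four
    columns IID MARKER REP VALUE in that order.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    if not first:
        log.warning("measurement file %s is empty", path)
        return MeasurementSet(pd.DataFrame(columns=_MEAS_COLUMNS))

    tokens = [t.lower() for t in first.split()]
    has_header = tokens[0] in _HEADER_ALIASES
    df = pd.read_csv(path, sep=r"\s+", header=0 if has_header else None)
    if has_header:
        df.columns = [_HEADER_ALIASES.get(str(c).lower(), str(c)) for c in df.columns]
        missing = set(_MEAS_COLUMNS) - set(df.columns)
        if missing:
            raise PedigreeError(f"measurement file missing columns: {sorted(missing)}")
        df = df[_MEAS_COLUMNS]
    else:
        if df.shape[1] != 4:
            raise PedigreeError(
                f"headerless measurement file must have 4 columns, got {df.shape[1]}"
            )
        df.columns = _MEAS_COLUMNS

    df["individual_id"] = df["individual_id"].astype(str)
    df["marker_id"] = df["marker_id"].astype(str)
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        bad = df.loc[values.isna()].iloc[0]
        raise PedigreeError(
            f"non-numeric measurement value {bad['value']!r} for "
            f"individual {bad['individual_id']!r}"
        )
    if not np.isfinite(values).all():
        raise PedigreeError("measurement values must be finite")
    df["value"] = values.astype(float)

    known = set(pedigree.individuals)
    unknown = sorted(set(df["individual_id"]) - known)
    if unknown:
        raise PedigreeError(f"measurement IDs not in pedigree: {unknown[:5]}")

    ms = MeasurementSet(df.reset_index(drop=True))
    counts = ms.replicate_counts()
    if not counts.empty:
        log.info(
            "read %d measurements for %d individual/marker combinations "
            "(replicate counts: %s)",
            len(ms),
            len(counts),
            dict(counts.value_counts().sort_index()),
        )
    return ms


# ---------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.6f"


def write_posteriors(
    summary: PosteriorSummary, path: str | Path, flags_path: str | Path | None = None
) -> None:
    """Write per-individual posterior summaries (and family flags) as TSV.

    ``path`` receives one row per individual/marker with the posterior
    mass over integer copy numbers, the posterior mean CN and mutation
    probabilities; family-level flags at each configured threshold go to
    ``flags_path`` (default: ``<path>`` with a ``.flags.tsv`` suffix).
    """
    path = Path(path)
    summary.individuals.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if summary.family_flags is not None:
        if flags_path is None:
            flags_path = path.with_suffix(".flags.tsv")
        summary.family_flags.to_csv(
            flags_path, sep="\t", index=False, float_format=_FLOAT_FMT
        )


def read_posteriors(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_association(fit: AssociationFit, path: str | Path) -> None:
    """Write an association summary table (term, mean, sd, P(beta>0)%, OR)."""
    fit.table.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)


def read_association(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pedigree(ped: Pedigree, path: str | Path, phenotype_coding: str = "ped") -> None:
    """Inverse of :func:`read_pedigree` (used by the simulator CLI)."""
    lines = []
    for fam in ped.families.values():
        for ind in fam.members.values():
            if ind.affected is None:
                pheno = "0" if phenotype_coding == "ped" else "-9"
            elif phenotype_coding == "ped":
                pheno = "2" if ind.affected else "1"
            else:
                pheno = "1" if ind.affected else "0"
            row = [
                fam.family_id,
                ind.individual_id,
                ind.father_id or MISSING_PARENT,
                ind.mother_id or MISSING_PARENT,
                str(ind.sex or 0),
                pheno,
            ] + [_FLOAT_FMT % c for c in ind.covariates]
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def write_measurements(ms: MeasurementSet, path: str | Path) -> None:
    ms.data.to_csv(Path(path), sep="\t", index=False, float_format=_FLOAT_FMT)
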