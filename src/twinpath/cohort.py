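"""Family-structured cohort tables: reading, validation, writing.

The on-disk format is a CSV with one row per family: ``family_id``,
``zygosity`` (MZ/DZ), then per-member suffixed columns ``<name>_t1`` /
``<name>_t2`` for every phenotype and covariate.  Missing values are written
as empty fields; both empty fields and ``NA`` are read as missing.  Free-text
provenance is carried in ``# key: value`` comment lines before the header.

Coding conventions (fixed, documented): binary phenotypes 0 = unaffected,
1 = affected; sex 0 = male, 1 = female.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .model import ModelError, VariableSpec

ZYGOSITIES = ("MZ", "DZ")
_MISSING_STRINGS = {"", "NA", "na", "NaN", "nan"}


class CohortError(ValueError):
    """Structured cohort parse/validation error."""


@dataclass
class Member:
    """One twin's phenotype values (NaN = missing) and covariates."""

    phenotypes: dict
    covariates: dict

    def observed(self, name: str) -> bool:
        v = self.phenotypes.get(name, np.nan)
        return v is not None and np.isfinite(v)

    def all_missing(self) -> bool:
        return not any(self.observed(k) for k in self.phenotypes)


@dataclass
class FamilyRecord:
    """One family: zygosity, up to two member slots."""

    family_id: str
    zygosity: str
    members: list

    def validate(self, variables):
        if self.zygosity not in ZYGOSITIES:
            raise CohortError(
                f"family {self.family_id!r}: unknown zygosity "
                f"{self.zygosity!r}"
            )
        if not 1 <= len(self.members) <= 2:
            raise CohortError(
                f"family {self.family_id!r}: {len(self.members)} members; "
                "twin design allows 1 or 2"
            )
        by_name = {v.name: v for v in variables}
        for m, member in enumerate(self.members, start=1):
            for name, value in member.phenotypes.items():
                if name not in by_name:
                    raise CohortError(
                        f"family {self.family_id!r}: phenotype {name!r} not "
                        "declared in variable specs"
                    )
                if value is None or (isinstance(value, float)
                                     and np.isnan(value)):
                    continue
                if by_name[name].is_binary and value not in (0.0, 1.0):
                    raise CohortError(
                        f"family {self.family_id!r} member {m}: binary "
                        f"variable {name!r} has value {value!r} outside "
                        "{0, 1, missing}"
                    )
                if not np.isfinite(value):
                    raise CohortError(
                        f"family {self.family_id!r} member {m}: non-finite "
                        f"value for {name!r}"
                    )
        if len(self.members) == 2 and all(
                m.all_missing() for m in self.members):
            # an all-missing pair is inert but permitted only one-sided
            raise CohortError(
                f"family {self.family_id!r}: both members have all "
                "phenotypes missing"
            )


@dataclass
class TwinDataset:
    """Ordered variable specs plus validated family records."""

    variables: tuple
    families: list
    covariates: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.variables = tuple(self.variables)
        self.covariates = tuple(self.covariates)

    def validate(self):
        seen = set()
        for fam in self.families:
            if fam.family_id in seen:
                raise CohortError(f"duplicate family_id {fam.family_id!r}")
            seen.add(fam.family_id)
            fam.validate(self.variables)
        return self

    def zygosity_counts(self) -> dict:
        counts = {z: 0 for z in ZYGOSITIES}
        for fam in self.families:
            counts[fam.zygosity] += 1
        return counts

    def variable(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise CohortError(f"unknown variable {name!r}")

    def values(self, name: str) -> np.ndarray:
        """All members' values of a phenotype, NaN for missing, flattened."""
        out = []
        for fam in self.families:
            for member in fam.members:
                out.append(member.phenotypes.get(name, np.nan))
        return np.asarray(out, dtype=float)

    def pair_values(self, name: str, zygosity=None) -> np.ndarray:
        """(n, 2) array of the phenotype for two-member families."""
        rows = []
        for fam in self.families:
            if zygosity is not None and fam.zygosity != zygosity:
                continue
            if len(fam.members) != 2:
                continue
            rows.append([m.phenotypes.get(name, np.nan)
                         for m in fam.members])
        return np.asarray(rows, dtype=float).reshape(-1, 2)

    def subset(self, family_ids) -> "TwinDataset":
        wanted = list(family_ids)
        by_id = {f.family_id: f for f in self.families}
        fams = [by_id[i] for i in wanted]
        return TwinDataset(self.variables, fams, self.covariates,
                           dict(self.provenance))


# --------------------------------------------------------------------- #
# variable specification files


def load_variable_specs(source):
    """Load variable specs from a YAML path/dict/list of VariableSpec."""
    if isinstance(source, (list, tuple)) and all(
            isinstance(v, VariableSpec) for v in source):
        return tuple(source), ()
    if isinstance(source, (str,)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    if not isinstance(source, dict) or "variables" not in source:
        raise CohortError("variable spec must contain a 'variables' list")
    variables = []
    for entry in source["variables"]:
        scale = entry.get("scale", "binary_liability")
        if scale == "binary":
            scale = "binary_liability"
        variables.append(VariableSpec(
            name=entry["name"],
            scale=scale,
            components_allowed=tuple(entry.get("components", ("A", "C", "E"))),
            covariates=tuple(entry.get("covariates", ())),
        ))
    covariates = tuple(source.get("covariates", ()))
    return tuple(variables), covariates


def dump_variable_specs(variables, covariates=(), path=None):
    doc = {
        "variables": [
            {
                "name": v.name,
                "scale": v.scale,
                "components": list(v.components_allowed),
                "covariates": list(v.covariates),
            }
            for v in variables
        ],
        "covariates": list(covariates),
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# --------------------------------------------------------------------- #
# read / write


def _parse_cell(raw, line_no, col):
    if raw is None:
        return np.nan
    s = str(raw).strip()
    if s in _MISSING_STRINGS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise CohortError(
            f"line {line_no}: cannot parse {raw!r} in column {col!r}"
        ) from None


def read_cohort(path, spec) -> TwinDataset:
    """Read and validate a per-family CSV into a :class:`TwinDataset`.

    ``spec`` is a variable-spec source accepted by
    :func:`load_variable_specs`.  Rows with unknown zygosity codes or
    out-of-range binary values raise :class:`CohortError` naming the row.
    """
    variables, covariates = load_variable_specs(spec)
    provenance = {}
    header = None
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    provenance[key.strip()] = val.strip()
                continue
            cells = line.split(",")
            if header is None:
                header = [c.strip() for c in cells]
                continue
            if len(cells) != len(header):
                raise CohortError(
                    f"line {line_no}: {len(cells)} fields, expected "
                    f"{len(header)}"
                )
            rows.append((line_no, dict(zip(header, cells))))
    if header is None:
        raise CohortError(f"{path}: no header row")
    needed = {"family_id", "zygosity"}
    missing_cols = needed - set(header)
    if missing_cols:
        raise CohortError(f"missing required columns {sorted(missing_cols)}")
    stems = [v.name for v in variables] + list(covariates)
    for stem in stems:
        if f"{stem}_t1" not in header:
            raise CohortError(f"missing column {stem}_t1")
    families = []
    for line_no, row in rows:
        fam_id = row["family_id"].strip()
        zyg = row["zygosity"].strip()
        if zyg not in ZYGOSITIES:
            raise CohortError(
                f"line {line_no}: unknown zygosity code {zyg!r} for family "
                f"{fam_id!r}"
            )
        members = []
        for t in (1, 2):
            phen = {}
            cov = {}
            any_col = False
            for v in variables:
                col = f"{v.name}_t{t}"
                if col in row:
                    any_col = True
                    phen[v.name] = _parse_cell(row[col], line_no, col)
            for c in covariates:
                col = f"{c}_t{t}"
                if col in row:
                    cov[c] = _parse_cell(row[col], line_no, col)
            if any_col:
                members.append(Member(phenotypes=phen, covariates=cov))
        families.append(FamilyRecord(fam_id, zyg, members))
    ds = TwinDataset(variables, families, covariates, provenance)
    ds.validate()
    return ds


def write_cohort(ds: TwinDataset, path) -> None:
    """Write a dataset so that :func:`read_cohort` round-trips it exactly."""
    cols = ["family_id", "zygosity"]
    stems = [v.name for v in ds.variables] + list(ds.covariates)
    for t in (1, 2):
        cols += [f"{s}_t{t}" for s in stems]
    with open(path, "w") as fh:
        for key, val in ds.provenance.items():
            fh.write(f"# {key}: {val}\n")
        fh.write(",".join(cols) + "\n")
        for fam in ds.families:
            row = [fam.family_id, fam.zygosity]
            for t in (1, 2):
                member = fam.members[t - 1] if len(fam.members) >= t else None
                for v in ds.variables:
                    row.append(_format_cell(
                        member.phenotypes.get(v.name, np.nan)
                        if member else np.nan))
                for c in ds.covariates:
                    row.append(_format_cell(
                        member.covariates.get(c, np.nan)
                        if member else np.nan))
            fh.write(",".join(row) + "\n")


def _format_cell(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    return repr(float(value))


def to_dataframe(ds: TwinDataset) -> pd.DataFrame:
    """Member-level long view: one row per individual."""
    rows = []
    for fam in ds.families:
        for t, member in enumerate(fam.members, start=1):
            rec = {"family_id": fam.family_id, "zygosity": fam.zygosity,
                   "member": t}
            rec.update({v.name: member.phenotypes.get(v.name, np.nan)
                        for v in ds.variables})
            rec.update({c: member.covariates.get(c, np.nan)
                        for c in ds.covariates})
            rows.append(rec)
    return pd.DataFrame(rows)


def standardize_prs(ds: TwinDataset, variable: str) -> TwinDataset:
    """Return a dataset with a continuous variable z-scored over observed
    values (sample SD, divisor n-1); missingness pattern unchanged."""
    spec = ds.variable(variable)
    if spec.is_binary:
        raise CohortError(f"{variable!r} is not continuous")
    vals = ds.values(variable)
    obs = vals[np.isfinite(vals)]
    if obs.size < 2:
        raise CohortError(f"{variable!r}: fewer than 2 observed values")
    sd = obs.std(ddof=1)
    if sd == 0:
        raise CohortError(f"{variable!r} has zero variance")
    mean = obs.mean()
    new_fams = []
    for fam in ds.families:
        members = []
        for member in fam.members:
            phen = dict(member.phenotypes)
            if variable in phen and np.isfinite(phen[variable]):
                phen[variable] = (phen[variable] - mean) / sd
            members.append(Member(phen, dict(member.covariates)))
        new_fams.append(FamilyRecord(fam.family_id, fam.zygosity, members))
    return TwinDataset(ds.variables, new_fams, ds.covariates,
                       dict(ds.provenance))
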