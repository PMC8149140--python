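"""CSV ingest and export for the four study tables.

All files are comma-separated UTF-8 with a mandatory header, ``.`` decimal
separator and empty strings for missing values.  The gut table is long
format: one row per (fish, food category) plus one ``_fullness`` row per
fish carrying the total gut fullness.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .records import (CommunityCount, FishRecord, GutSample, IsotopeSample,
                      ValidationError)

__all__ = ["SchemaError", "read_table", "write_table", "FULLNESS_ROW"]

FULLNESS_ROW = "_fullness"

_COLUMNS = {
    "fish": ["fish_id", "population_id", "status", "total_length_cm",
             "weight_g", "age", "pass_number"],
    "gut": ["fish_id", "population_id", "total_length_cm", "category",
            "volume_pct"],
    "isotope": ["sample_id", "group", "taxon", "population_id", "d13C",
                "d15N", "c_to_n"],
    "community": ["site_id", "taxon", "count", "area_m2"],
}


class SchemaError(ValueError):
    """The file header does not match the declared schema."""


def _load(path: str | Path, schema: str) -> pd.DataFrame:
    if schema not in _COLUMNS:
        raise SchemaError(f"unknown schema {schema!r}; "
                          f"expected one of {sorted(_COLUMNS)}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} "
                          f"for schema {schema!r}")
    return df


def _opt_float(value: str) -> float | None:
    return None if value == "" else float(value)


def _opt_int(value: str) -> int | None:
    return None if value == "" else int(float(value))


def _row_error(schema: str, idx: int, exc: Exception) -> ValidationError:
    return ValidationError(f"{schema} row {idx}: {exc}")


def read_table(path: str | Path, schema: str):
    """Read and validate one of the study tables.

    Parameters
    ----------
    path : path to a CSV file
    schema : one of ``fish``, ``gut``, ``isotope``, ``community``

    Returns
    -------
    list of the matching record type, in file row order (gut rows are
    grouped into one :class:`GutSample` per fish, in first-appearance
    order).
    """
    df = _load(path, schema)
    if schema == "fish":
        out = []
        for idx, row in enumerate(df.itertuples(index=False)):
            try:
                out.append(FishRecord(
                    fish_id=row.fish_id,
                    population_id=row.population_id,
                    status=row.status,
                    total_length=float(row.total_length_cm),
                    weight=_opt_float(row.weight_g),
                    age=_opt_int(row.age),
                    pass_number=_opt_int(row.pass_number),
                ))
            except (ValueError, ValidationError) as exc:
                raise _row_error(schema, idx, exc) from exc
        return out
    if schema == "gut":
        return _read_gut(df)
    if schema == "isotope":
        out = []
        for idx, row in enumerate(df.itertuples(index=False)):
            try:
                out.append(IsotopeSample(
                    sample_id=row.sample_id,
                    group=row.group,
                    taxon=row.taxon,
                    population_id=row.population_id,
                    d13C=float(row.d13C),
                    d15N=float(row.d15N),
                    c_to_n=_opt_float(row.c_to_n),
                ))
            except (ValueError, ValidationError) as exc:
                raise _row_error(schema, idx, exc) from exc
        return out
    out = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            out.append(CommunityCount(
                site_id=row.site_id,
                taxon=row.taxon,
                count=int(float(row.count)),
                area=float(row.area_m2),
            ))
        except (ValueError, ValidationError) as exc:
            raise _row_error(schema, idx, exc) from exc
    return out


def _read_gut(df: pd.DataFrame) -> list[GutSample]:
    order: list[str] = []
    meta: dict[str, tuple[str, float]] = {}
    fullness: dict[str, float] = {}
    items: dict[str, dict[str, float]] = {}
    for idx, row in enumerate(df.itertuples(index=False)):
        fid = row.fish_id
        if fid not in meta:
            order.append(fid)
            meta[fid] = (row.population_id, float(row.total_length_cm))
            items[fid] = {}
        if row.category == FULLNESS_ROW:
            fullness[fid] = float(row.volume_pct)
        else:
            items[fid][row.category] = items[fid].get(row.category, 0.0) \
                + float(row.volume_pct)
    out = []
    for idx, fid in enumerate(order):
        pop, tl = meta[fid]
        if fid not in fullness:
            raise ValidationError(
                f"gut fish {fid!r}: missing {FULLNESS_ROW} row")
        try:
            out.append(GutSample(
                fish_id=fid, population_id=pop, total_length=tl,
                fullness=fullness[fid],
                items={k: v for k, v in items[fid].items() if v != 0.0},
            ))
        except ValidationError as exc:
            raise _row_error("gut", idx, exc) from exc
    return out


def write_table(records, schema: str, path: str | Path) -> None:
    """Write records back to CSV in the same schema ``read_table`` expects."""
    if schema not in _COLUMNS:
        raise SchemaError(f"unknown schema {schema!r}")
    rows: list[dict] = []
    if schema == "fish":
        for r in records:
            rows.append({
                "fish_id": r.fish_id, "population_id": r.population_id,
                "status": r.status,
                "total_length_cm": repr(r.total_length),
                "weight_g": "" if r.weight is None else repr(r.weight),
                "age": "" if r.age is None else r.age,
                "pass_number": "" if r.pass_number is None else r.pass_number,
            })
    elif schema == "gut":
        for r in records:
            base = {"fish_id": r.fish_id, "population_id": r.population_id,
                    "total_length_cm": repr(r.total_length)}
            rows.append(dict(base, category=FULLNESS_ROW,
                             volume_pct=repr(r.fullness)))
            for cat in sorted(r.items):
                rows.append(dict(base, category=cat,
                                 volume_pct=repr(r.items[cat])))
    elif schema == "isotope":
        for r in records:
            rows.append({
                "sample_id": r.sample_id, "group": r.group, "taxon": r.taxon,
                "population_id": r.population_id,
                "d13C": repr(r.d13C), "d15N": repr(r.d15N),
                "c_to_n": "" if r.c_to_n is None else repr(r.c_to_n),
            })
    else:
        for r in records:
            rows.append({"site_id": r.site_id, "taxon": r.taxon,
                         "count": r.count, "area_m2": repr(r.area)})
    pd.DataFrame(rows, columns=_COLUMNS[schema]).to_csv(path, index=False)
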