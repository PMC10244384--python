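"""Tab-separated readers and writers for every table the pipeline consumes.

All tables are UTF-8 TSV with a header row, decimal points and no thousands
separators, and every writer's output is re-readable by the matching reader.
Clonotype and repertoire tables follow AIRR-style column naming where one
exists (``cdr3_aa``/``junction_aa``, ``duplicate_count``).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .atchley import TcrDistanceMatrix
from .core import ContactCounts, ExposureProfile, TcrClonotype, validate_cdr3

PathLike = Union[str, Path]

_CLONOTYPE_OPTIONAL = ("pmhc", "compartment", "count", "halflife_s", "v_gene", "j_gene")


def read_clonotype_table(path: PathLike, strict: bool = False) -> list[TcrClonotype]:
    """Read a clonotype table (required columns ``tcr_id``, ``cdr3b``).

    Optional columns (pmhc, compartment, count, halflife_s, v_gene, j_gene)
    are picked up when present; unknown columns are tolerated. Malformed rows
    are reported with their line number — skipped with a warning by default,
    or failing the whole file when ``strict`` is set. CDR3b sequences are
    upper-cased.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty and df.columns.empty:
        raise ValueError(f"{path}: empty file")
    missing = [c for c in ("tcr_id", "cdr3b") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out: list[TcrClonotype] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            kwargs = {}
            for col in _CLONOTYPE_OPTIONAL:
                val = row.get(col)
                if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                    continue
                if col == "count":
                    kwargs[col] = int(val)
                elif col == "halflife_s":
                    kwargs[col] = float(val)
                else:
                    kwargs[col] = str(val)
            out.append(TcrClonotype(tcr_id=str(row["tcr_id"]), cdr3b=str(row["cdr3b"]), **kwargs))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line_no}: {exc}")
    if errors:
        message = f"{path}: {len(errors)} malformed row(s): " + "; ".join(errors)
        if strict:
            raise ValueError(message)
        warnings.warn(message, UserWarning, stacklevel=2)
    if not out:
        raise ValueError(f"{path}: no valid clonotype rows")
    return out


def write_clonotype_table(clonotypes: Sequence[TcrClonotype], path: PathLike) -> None:
    rows = [
        {
            "tcr_id": c.tcr_id,
            "cdr3b": c.cdr3b,
            "pmhc": c.pmhc,
            "compartment": c.compartment,
            "count": c.count,
            "halflife_s": c.halflife_s,
            "v_gene": c.v_gene,
            "j_gene": c.j_gene,
        }
        for c in clonotypes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_exposure_table(path: PathLike) -> dict[str, ExposureProfile]:
    """Read a long exposure table (tcr_id, position, exposed_fraction).

    Positions are 1-based and must be contiguous from 1 for each TCR.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("tcr_id", "position", "exposed_fraction") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    profiles: dict[str, ExposureProfile] = {}
    for tcr_id, group in df.groupby("tcr_id", sort=False):
        group = group.sort_values("position")
        positions = group["position"].to_numpy(dtype=int)
        if not np.array_equal(positions, np.arange(1, len(positions) + 1)):
            raise ValueError(
                f"{path}: positions for {tcr_id!r} are not contiguous from 1"
            )
        profiles[str(tcr_id)] = ExposureProfile(
            tcr_id=str(tcr_id),
            exposed_fraction=group["exposed_fraction"].to_numpy(dtype=float),
        )
    if not profiles:
        raise ValueError(f"{path}: no exposure rows")
    return profiles


def write_exposure_table(
    profiles: Sequence[ExposureProfile], path: PathLike
) -> None:
    rows = [
        {"tcr_id": p.tcr_id, "position": i + 1, "exposed_fraction": frac}
        for p in profiles
        for i, frac in enumerate(p.exposed_fraction)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contact_table(path: PathLike) -> list[ContactCounts]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("complex_id", "n_apolar", "n_polar") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for _, row in df.iterrows():
        halflife = row.get("halflife_s")
        out.append(
            ContactCounts(
                complex_id=str(row["complex_id"]),
                n_apolar=int(row["n_apolar"]),
                n_polar=int(row["n_polar"]),
                halflife_s=None if pd.isna(halflife) else float(halflife),
            )
        )
    if not out:
        raise ValueError(f"{path}: no contact rows")
    return out


def write_contact_table(records: Sequence[ContactCounts], path: PathLike) -> None:
    rows = [
        {
            "complex_id": r.complex_id,
            "n_apolar": r.n_apolar,
            "n_polar": r.n_polar,
            "halflife_s": r.halflife_s,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_distance_matrix(matrix: TcrDistanceMatrix, path: PathLike) -> None:
    """Square TSV with tcr_ids as header row and index column."""
    matrix.to_dataframe().to_csv(path, sep="\t", index_label="tcr_id")


def read_distance_matrix(path: PathLike) -> TcrDistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column ids differ")
    return TcrDistanceMatrix(ids=[str(i) for i in df.columns], values=df.to_numpy(dtype=float))


def write_distance_long(matrix: TcrDistanceMatrix, path: PathLike) -> None:
    matrix.to_long().to_csv(path, sep="\t", index=False)


def read_repertoire_table(path: PathLike) -> pd.DataFrame:
    """Read a bulk repertoire table with AIRR-compatible column names.

    Accepts ``cdr3_aa`` or ``junction_aa`` for the sequence column and
    ``count`` or ``duplicate_count`` for read counts; ``v_gene``/``j_gene``
    (or ``v_call``/``j_call``) are optional.
    """
    df = pd.read_csv(path, sep="\t")
    renames = {"junction_aa": "cdr3_aa", "duplicate_count": "count",
               "v_call": "v_gene", "j_call": "j_gene"}
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    missing = [c for c in ("cdr3_aa", "count") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for seq in df["cdr3_aa"]:
        validate_cdr3(str(seq))
    df["count"] = df["count"].astype(int)
    if (df["count"] < 1).any():
        raise ValueError(f"{path}: read counts must be >= 1")
    return df


def write_keyvalues(values: Mapping[str, object], path: PathLike) -> None:
    """Serialize a flat mapping as ``key<TAB>value`` text, one per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in values.items():
            fh.write(f"{key}\t{val}\n")


def read_keyvalues(path: PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, val = line.partition("\t")
            out[key] = val
    return out


def write_logistic_model(results, path: PathLike) -> None:
    """Serialize a fitted logistic classifier, feature definition inline."""
    fdef = results.fdef
    values: dict[str, object] = {
        "model": "avidity_logistic",
        "b0": repr(results.b0),
        "ridge": repr(results.ridge),
        "separable": results.separable,
        "threshold": repr(results.threshold),
    }
    if fdef is not None:
        values["residues"] = "".join(fdef.residues)
        values["encoding"] = fdef.encoding
        values["exposure_threshold"] = repr(fdef.exposure_threshold)
        for r, w in zip(fdef.residues, results.weights):
            values[f"W[{r}]"] = repr(float(w))
    else:
        for i, w in enumerate(results.weights):
            values[f"W{i + 1}"] = repr(float(w))
    write_keyvalues(values, path)
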