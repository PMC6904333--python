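"""Readers and writers for every external format the pipeline touches.

Expression matrices and clinical tables are plain delimited text;
signatures use a small versioned key/value + pair-table format so that
pairs, coefficients and the cutoff round-trip atomically.  All floats
are serialized with ``repr`` (17 significant digits), so write -> read
is exact.
"""
from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (ClinicalTable, DomainError, ExpressionMatrix, ParseError,
                        SchemaError, SignatureModel)

__all__ = [
    "read_expression",
    "write_expression",
    "read_clinical",
    "read_clinical_canonical",
    "write_clinical",
    "read_signature",
    "write_signature",
    "load_published_signature",
    "DAYS_PER_MONTH",
]

#: average Gregorian month length, used to convert day-denominated times
DAYS_PER_MONTH = 30.4375

SIGNATURE_MAGIC = "pairsig-signature"
SIGNATURE_VERSION = 1


def read_expression(path, delimiter: str = "\t", units: str = "arbitrary",
                    log_scale: bool = False) -> ExpressionMatrix:
    """Read a genes-in-rows delimited expression table.

    First column holds gene ids, the header row sample ids.  Duplicate
    gene ids (e.g. multiple probes per RNA) are collapsed to their
    per-gene mean, and rows are sorted by gene id so the result is
    independent of input row order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, index_col=0, keep_default_na=False,
                     na_values=[], dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: empty expression matrix")
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise ParseError(
                f"{path}: non-numeric value {df.loc[gene, col]!r} at "
                f"gene {gene!r}, sample {col!r}")
        numeric[col] = converted
    if numeric.index.has_duplicates:
        numeric = numeric.groupby(level=0, sort=True).mean()
    else:
        numeric = numeric.sort_index()
    return ExpressionMatrix.from_frame(numeric, units=units, log_scale=log_scale)


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    expr.to_frame().to_csv(path, sep=delimiter, float_format="%.9g")


_AGE_LABELS = {"<18 months": 0, ">=18 months": 1, "≥18 months": 1}
_STAGE4 = {"4": 1, "1": 0, "2": 0, "3": 0, "4S": 0, "4s": 0}
_SEX = {"male": 1, "m": 1, "female": 0, "f": 0}
_MYCN = {"amplified": 1, "not amplified": 0, "non-amplified": 0}
_MISSING = {"", "na", "nan", "unknown", "missing", "-", "–"}


def _map_cat(raw, table: Mapping[str, int], field: str):
    if pd.isna(raw):
        return np.nan
    s = str(raw).strip()
    if s.lower() in _MISSING:
        return np.nan
    if s in ("0", "1"):
        return int(s)
    key = s if s in table else s.lower()
    if key in table:
        return table[key]
    raise DomainError(f"unmapped {field} value: {s!r}")


def read_clinical(path, column_map: Mapping[str, str], delimiter: str = "\t",
                  time_unit: str = "months") -> ClinicalTable:
    """Read a per-sample clinical table.

    ``column_map`` maps canonical field names to file column names.
    Recognised canonical names: ``sample_id``, ``sex``, ``age``
    (label "<18 months"/">=18 months" or 0/1), ``mycn``, ``stage``
    (1/2/3/4/4S or 0/1), and per-endpoint ``os_time``, ``os_event``,
    ``efs_time``, ``efs_event``.  Times in days are converted to months
    (``time_unit="days"``).
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    if "sample_id" not in column_map:
        raise SchemaError("column_map must provide 'sample_id'")
    for canonical, col in column_map.items():
        if col not in raw.columns:
            raise SchemaError(f"{path}: column {col!r} (for {canonical!r}) not found")
    out = pd.DataFrame(index=pd.Index(raw[column_map["sample_id"]].astype(str),
                                      name="sample_id"))
    if out.index.has_duplicates:
        raise DomainError(f"{path}: duplicate sample ids")

    def col(name):
        return raw[column_map[name]].to_numpy() if name in column_map else None

    if (v := col("sex")) is not None:
        out["sex"] = [_map_cat(x, _SEX, "sex") for x in v]
    if (v := col("age")) is not None:
        out["age_ge_18m"] = [_map_cat(x, _AGE_LABELS, "age") for x in v]
    if (v := col("mycn")) is not None:
        out["mycn_amplified"] = [_map_cat(x, _MYCN, "MYCN") for x in v]
    if (v := col("stage")) is not None:
        out["stage4"] = [_map_cat(x, _STAGE4, "stage") for x in v]

    scale = 1.0 / DAYS_PER_MONTH if time_unit == "days" else 1.0
    for pre in ("os", "efs"):
        tname, ename = f"{pre}_time", f"{pre}_event"
        if tname in column_map:
            t = pd.to_numeric(raw[column_map[tname]], errors="coerce") * scale
            if (t.dropna() < 0).any():
                raise DomainError(f"{path}: negative {tname}")
            e = pd.to_numeric(raw[column_map[ename]], errors="coerce")
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise DomainError(f"{path}: {ename} value {bad.iloc[0]!r} not in {{0,1}}")
            out[tname] = t.to_numpy()
            out[ename] = e.to_numpy()
    return ClinicalTable(out)


def write_clinical(clinical: ClinicalTable, path, delimiter: str = "\t") -> None:
    """Write a clinical table in the canonical column layout."""
    clinical.data.to_csv(path, sep=delimiter, index_label="sample_id",
                         float_format="%.9g")


def read_clinical_canonical(path, delimiter: str = "\t") -> ClinicalTable:
    """Read a clinical table already in the canonical layout (as written
    by :func:`write_clinical`): sample_id index plus any of the columns
    sex, age_ge_18m, mycn_amplified, stage4, os_time, os_event,
    efs_time, efs_event, all numeric with blanks for missing."""
    df = pd.read_csv(path, sep=delimiter, index_col="sample_id")
    df.index = df.index.astype(str)
    for col in df.columns:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for pre in ("os", "efs"):
        tcol = f"{pre}_time"
        if tcol in df.columns and (df[tcol].dropna() < 0).any():
            raise DomainError(f"{path}: negative {tcol}")
        ecol = f"{pre}_event"
        if ecol in df.columns:
            bad = df[ecol].dropna()[~df[ecol].dropna().isin([0, 1])]
            if len(bad):
                raise DomainError(f"{path}: {ecol} outside {{0,1}}")
    return ClinicalTable(df)


def write_signature(model: SignatureModel, path) -> None:
    """Serialize a signature to the versioned single-document text format."""
    lines = [f"{SIGNATURE_MAGIC}\t{SIGNATURE_VERSION}"]
    meta = dict(model.metadata)
    lines.append(f"endpoint\t{meta.pop('endpoint', 'OS')}")
    lines.append(f"label\t{meta.pop('label', 'unlabelled')}")
    for k, v in meta.items():
        lines.append(f"{k}\t{v}")
    lines.append("cutoff\t" + ("none" if model.cutoff is None else repr(float(model.cutoff))))
    lines.append(f"cutoff_method\t{model.cutoff_method}")
    lines.append(f"n_pairs\t{len(model.pairs)}")
    lines.append("gene1\tgene2\tcoefficient")
    for (g1, g2), beta in zip(model.pairs, model.coefficients):
        lines.append(f"{g1}\t{g2}\t{float(beta)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_signature(path) -> SignatureModel:
    """Parse a signature file written by :func:`write_signature`."""
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines or not lines[0].startswith(SIGNATURE_MAGIC):
        raise SchemaError(f"{path}: not a pairsig signature file")
    meta: dict[str, str] = {}
    i = 1
    while i < len(lines) and not lines[i].startswith("gene1\t"):
        parts = lines[i].split("\t", 1)
        if len(parts) != 2:
            raise SchemaError(f"{path}: malformed header line {lines[i]!r}")
        meta[parts[0]] = parts[1]
        i += 1
    for required in ("cutoff", "cutoff_method", "n_pairs"):
        if required not in meta:
            raise SchemaError(f"{path}: missing field {required!r}")
    cutoff = None if meta["cutoff"] == "none" else float(meta["cutoff"])
    pairs: list[tuple[str, str]] = []
    coefs: list[float] = []
    for ln in lines[i + 1:]:
        parts = ln.split("\t")
        if len(parts) != 3:
            raise SchemaError(f"{path}: malformed pair line {ln!r}")
        pairs.append((parts[0], parts[1]))
        try:
            coefs.append(float(parts[2]))
        except ValueError:
            raise SchemaError(f"{path}: non-numeric coefficient in {ln!r}") from None
    if len(pairs) != int(meta["n_pairs"]):
        raise SchemaError(f"{path}: n_pairs={meta['n_pairs']} but "
                          f"{len(pairs)} pair lines")
    if not pairs:
        warnings.warn(f"{path}: signature file contains zero pairs", stacklevel=2)
    extra = {k: v for k, v in meta.items()
             if k not in ("cutoff", "cutoff_method", "n_pairs")}
    return SignatureModel(pairs, np.array(coefs), cutoff=cutoff,
                          cutoff_method=meta["cutoff_method"], metadata=extra)


def load_published_signature() -> SignatureModel:
    """The bundled 10-pair neuroblastoma overall-survival signature.

    Ten gene pairs with their penalized-Cox coefficients and the
    ROC-derived risk-score cutoff of -4.774; the pair indicator is 1
    when the first gene's abundance is strictly below the second's.
    """
    ref = importlib.resources.files("pairsig") / "data" / "published_signature_os.txt"
    with importlib.resources.as_file(ref) as p:
        return read_signature(p)
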