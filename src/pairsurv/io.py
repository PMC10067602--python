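"""Readers and writers for the external formats the pipeline touches.

Expression matrices are plain delimited text (genes in rows by default),
clinical tables are delimited text with overall-survival time and event
columns, mutation calls come as MAF-lite TSV, gene sets as GMT, and fitted
pair-risk models as JSON.  Gene identifiers are HGNC-style symbols, matched
case-sensitively after whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

#: MAF variant classes counted as nonsynonymous by default (TMB denominator
#: conventions vary; this is the common exome panel convention).
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)

KNOWN_VARIANT_CLASSES = NONSYNONYMOUS_CLASSES | {
    "Silent",
    "3'UTR",
    "5'UTR",
    "3'Flank",
    "5'Flank",
    "Intron",
    "IGR",
    "RNA",
    "Targeted_Region",
}


class LoadError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass
class PairRiskModel:
    """A fitted gene-pair risk model.

    The per-sample risk score is ``exp(sum_i coef_i * indicator(pair_i))``
    where ``indicator(A|B) = 1`` iff expression of A exceeds expression of B
    within the sample.  ``cutoff`` thresholds the exponentiated score, so it
    must be positive; samples scoring strictly above it are called high risk.
    """

    terms: list[tuple[tuple[str, str], float]]
    cutoff: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [p for p, _ in self.terms]
        if len({frozenset(p) for p in pairs}) != len(pairs):
            raise ValueError("duplicate gene pairs (modulo orientation) in model terms")
        for (a, b), coef in self.terms:
            if a == b:
                raise ValueError(f"degenerate pair {a}|{a}")
            if not np.isfinite(coef):
                raise ValueError(f"non-finite coefficient for {a}|{b}")
        if not (self.cutoff > 0):
            raise ValueError("cutoff must be > 0 (it thresholds exp(sum))")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [p for p, _ in self.terms]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for (a, b), _ in self.terms:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)


def _read_delimited(path) -> pd.DataFrame:
    # sep=None sniffs tab vs comma from the header line
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_expression(path, orientation_hint: str = "genes_in_rows") -> pd.DataFrame:
    """Load an expression matrix as a genes x samples DataFrame.

    Parameters
    ----------
    path
        Tab- or comma-separated text with one header row; the first column
        holds gene identifiers (or sample identifiers when
        ``orientation_hint="samples_in_rows"``, in which case the table is
        transposed after loading).

    Duplicate gene rows are collapsed by their mean with a logged warning
    (the common microarray convention).  Any missing or non-numeric cell is
    a load error naming the offending position.
    """
    if orientation_hint not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation_hint {orientation_hint!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    names = [t.strip() for t in header.split(sep)[1:]]
    if orientation_hint == "genes_in_rows" and len(set(names)) != len(names):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise LoadError(f"duplicate sample ids: {dups}")
    df = _read_delimited(path)
    if orientation_hint == "samples_in_rows":
        df = df.T
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise LoadError(
                f"non-numeric cell at gene {row!r}, sample {col!r}: {df.loc[row, col]!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        row = df.isna().any(axis=1).idxmax()
        col = df.columns[df.loc[row].isna().argmax()]
        raise LoadError(f"missing value at gene {row!r}, sample {col!r}")

    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise LoadError(f"duplicate sample ids: {dups}")
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.warning("collapsing %d duplicate gene rows by mean", n_dup)
        df = df.groupby(level=0, sort=False).mean()
    if not np.isfinite(df.to_numpy()).all():
        raise LoadError("expression matrix contains non-finite values")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t")


_TIME_CANDIDATES = ("time", "os_time", "os.time", "survival_time", "futime", "days")
_EVENT_CANDIDATES = ("event", "os_event", "os.event", "status", "os", "death")

DEFAULT_EVENT_MAP = {"0": 0, "1": 1, 0: 0, 1: 1, 0.0: 0, 1.0: 1}


def read_clinical(
    path,
    time_col: str | None = None,
    event_col: str | None = None,
    event_map: dict | None = None,
) -> pd.DataFrame:
    """Load survival records as a DataFrame indexed by sample id.

    Returns columns ``time`` (non-negative, one unit per cohort, typically
    days) and ``event`` (1 = death observed, 0 = censored); every other input
    column is kept as a clinical covariate.  Rows lacking time or event are
    dropped and the count logged and stored in ``df.attrs["n_dropped"]``.
    """
    raw = _read_delimited(path)
    raw.index = raw.index.astype(str).str.strip()
    lower = {c.lower(): c for c in raw.columns}
    if time_col is None:
        time_col = next((lower[c] for c in _TIME_CANDIDATES if c in lower), None)
    if event_col is None:
        event_col = next((lower[c] for c in _EVENT_CANDIDATES if c in lower), None)
    if time_col is None or event_col is None:
        raise LoadError(
            f"could not identify time/event columns among {list(raw.columns)}"
        )

    emap = DEFAULT_EVENT_MAP if event_map is None else event_map
    time = pd.to_numeric(raw[time_col], errors="coerce")
    event = raw[event_col].map(lambda v: emap.get(v, np.nan))

    keep = time.notna() & event.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d records without survival information", n_dropped)
    df = pd.DataFrame({"time": time[keep].astype(float), "event": event[keep].astype(int)})
    covars = raw.loc[keep, [c for c in raw.columns if c not in (time_col, event_col)]]
    df = pd.concat([df, covars], axis=1)
    if (df["time"] < 0).any():
        bad = df.index[df["time"] < 0].tolist()
        raise LoadError(f"negative survival time for samples {bad}")
    if not df["event"].isin((0, 1)).all():
        raise LoadError("event values outside {0,1} after mapping")
    if df.index.duplicated().any():
        raise LoadError("duplicate sample ids in clinical table")
    df.attrs["n_dropped"] = n_dropped
    return df


def write_clinical(surv: pd.DataFrame, path) -> None:
    surv.to_csv(path, sep="\t", index_label="sample")


def read_maf_lite(path) -> pd.DataFrame:
    """Load a MAF-lite mutation table.

    Requires ``Hugo_Symbol``, ``Tumor_Sample_Barcode`` and
    ``Variant_Classification`` columns (extras ignored).  Unknown variant
    classes are kept with a warning.  An empty table is valid.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"MAF-lite missing mandatory columns: {missing}")
    out = df[required].rename(
        columns={
            "Hugo_Symbol": "gene",
            "Tumor_Sample_Barcode": "sample",
            "Variant_Classification": "variant_classification",
        }
    )
    for col in out.columns:
        out[col] = out[col].astype(str).str.strip()
    unknown = set(out["variant_classification"]) - KNOWN_VARIANT_CLASSES if len(out) else set()
    if unknown:
        logger.warning("unknown variant classes kept: %s", sorted(unknown))
    return out.reset_index(drop=True)


def write_maf_lite(mut: pd.DataFrame, path) -> None:
    mut.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample": "Tumor_Sample_Barcode",
            "variant_classification": "Variant_Classification",
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Load a GMT gene-set file: ``name<TAB>description<TAB>gene...`` per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise LoadError(f"GMT line {lineno}: fewer than 3 fields")
            name = fields[0].strip()
            if name in sets:
                raise LoadError(f"GMT duplicate set name {name!r}")
            genes = [g.strip() for g in fields[2:] if g.strip()]
            if not genes:
                raise LoadError(f"GMT set {name!r} is empty")
            if len(set(genes)) != len(genes):
                genes = list(dict.fromkeys(genes))
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def write_model(model: PairRiskModel, path) -> None:
    """Serialize a model to JSON.

    Coefficients and the cutoff are stored as decimal strings produced by
    ``repr(float)`` so that a write/read round trip is bit-exact on every
    platform.
    """
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "terms": [
            {"pair": [a, b], "coefficient": repr(float(coef))}
            for (a, b), coef in model.terms
        ],
        "cutoff": repr(float(model.cutoff)),
        "metadata": dict(model.metadata),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path) -> PairRiskModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise LoadError(f"unsupported model schema: {payload.get('schema_version')}")
    terms = [
        ((t["pair"][0], t["pair"][1]), float(t["coefficient"]))
        for t in payload["terms"]
    ]
    return PairRiskModel(
        terms=terms, cutoff=float(payload["cutoff"]), metadata=payload.get("metadata", {})
    )
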