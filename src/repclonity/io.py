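"""Readers and writers for clone tables, germline FASTA, expression and
clinical tables, plus the per-sample chain-presence matrix.

Two clone-table dialects are supported:

* ``airr`` — AIRR Rearrangement-style TSV with columns ``sample_id``,
  ``locus``, ``sequence``, ``duplicate_count`` (and optional ``v_call``).
* ``vdjer`` — a minimal assembler-output TSV with columns ``sequence``,
  ``count``, ``chain`` (optional ``sample_id``, ``v_call``).

Counts are treated as non-negative integer read counts. Identical sequences
within one (sample, chain) are merged by summing counts; zero-count rows are
dropped, and a (sample, chain) left with no clones is omitted entirely.
"""

from __future__ import annotations

import os
from collections import OrderedDict

import pandas as pd
from Bio import SeqIO

from ._errors import FormatError, RecordError
from .types import CHAINS, ClinicalRecord, CloneRecord, GermlineReference, Repertoire

_DIALECT_COLUMNS = {
    "airr": {"sample_id": "sample_id", "chain": "locus",
             "sequence": "sequence", "count": "duplicate_count"},
    "vdjer": {"sample_id": "sample_id", "chain": "chain",
              "sequence": "sequence", "count": "count"},
}


def read_clone_table(
    path: str | os.PathLike,
    dialect: str = "airr",
    library_sizes: dict[str, int] | None = None,
    default_sample_id: str = "sample",
) -> list[Repertoire]:
    """Read a clone table into one :class:`Repertoire` per (sample, chain).

    ``library_sizes`` maps sample_id to total RNA-seq reads (the sidecar
    table read by :func:`read_library_sizes`); repertoires for samples not
    listed get library_size 1 so abundance normalization is explicit opt-in.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'airr' or 'vdjer'")
    cols = _DIALECT_COLUMNS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [cols["sequence"], cols["count"], cols["chain"]]
    if dialect == "airr":
        required.append(cols["sample_id"])
    for col in required:
        if col not in df.columns:
            raise FormatError(f"clone table {path} is missing required column {col!r}")
    if cols["sample_id"] not in df.columns:
        df[cols["sample_id"]] = default_sample_id

    # merge duplicate sequences within (sample, chain); keep first v_call
    merged: OrderedDict[tuple[str, str], OrderedDict[str, list]] = OrderedDict()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        rec = row._asdict()
        chain = str(rec[cols["chain"]]).strip()
        if chain not in CHAINS:
            raise RecordError(f"unknown chain label {chain!r}", row=i)
        try:
            count = int(rec[cols["count"]])
        except (TypeError, ValueError):
            raise RecordError(
                f"count {rec[cols['count']]!r} is not an integer", row=i) from None
        if count < 0:
            raise RecordError(f"negative count {count}", row=i)
        if count == 0:
            continue
        sample = str(rec[cols["sample_id"]])
        seq = str(rec[cols["sequence"]]).upper()
        v_call = rec.get("v_call")
        if pd.isna(v_call):
            v_call = None
        key = (sample, chain)
        bucket = merged.setdefault(key, OrderedDict())
        if seq in bucket:
            bucket[seq][0] += count
        else:
            bucket[seq] = [count, v_call]

    repertoires = []
    for (sample, chain), bucket in merged.items():
        lib = (library_sizes or {}).get(sample, 1)
        clones = [
            CloneRecord(sample_id=sample, chain=chain, sequence=seq,
                        count=count, v_call=v_call)
            for seq, (count, v_call) in bucket.items()
        ]
        repertoires.append(Repertoire(sample_id=sample, chain=chain,
                                      clones=clones, library_size=lib))
    return repertoires


def write_clone_table(repertoires: list[Repertoire], path: str | os.PathLike,
                      dialect: str = "airr") -> None:
    """Write repertoires back to TSV in the given dialect (deterministic order)."""
    cols = _DIALECT_COLUMNS[dialect]
    rows = []
    for rep in repertoires:
        for clone in rep.clones:
            rows.append({
                cols["sample_id"]: rep.sample_id,
                cols["chain"]: rep.chain,
                cols["sequence"]: clone.sequence,
                cols["count"]: clone.count,
                "v_call": clone.v_call if clone.v_call is not None else "",
            })
    order = [cols["sample_id"], cols["chain"], cols["sequence"], cols["count"], "v_call"]
    pd.DataFrame(rows, columns=order).to_csv(path, sep="\t", index=False)


def read_germline_fasta(path: str | os.PathLike) -> GermlineReference:
    """Read a germline V-gene FASTA. Names are headers up to the first
    whitespace; sequences are upper-cased. Duplicate names are an error."""
    entries: dict[str, str] = {}
    duplicates = []
    n = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n += 1
        name = record.id
        if name in entries:
            duplicates.append(name)
            continue
        entries[name] = str(record.seq).upper()
    if n == 0:
        raise FormatError(f"germline FASTA {path} contains no records")
    if duplicates:
        raise FormatError(
            f"germline FASTA {path} has duplicate entries: {sorted(set(duplicates))}")
    return GermlineReference(entries=entries)


def read_library_sizes(path: str | os.PathLike) -> dict[str, int]:
    """Read the sidecar TSV mapping sample_id to total RNA-seq reads."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "total_reads"):
        if col not in df.columns:
            raise FormatError(f"library-size table {path} is missing column {col!r}")
    return dict(zip(df["sample_id"].astype(str), df["total_reads"].astype(int)))


def read_expression_matrix(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genes × samples matrix of log2 expression (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"expression matrix {path} has duplicate gene ids: {dupes}")
    if df.isna().any().any():
        raise FormatError(f"expression matrix {path} contains missing values")
    return df.astype(float)


def write_expression_matrix(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


_CLINICAL_OPTIONAL = ("age", "sex", "stage", "tissue_site", "response", "subtype")


def read_clinical_table(path: str | os.PathLike) -> list[ClinicalRecord]:
    """Read a clinical TSV with columns sample_id, os_time, os_event and any
    of age, sex, stage, tissue_site, response, subtype."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample_id", "os_time", "os_event"):
        if col not in df.columns:
            raise FormatError(f"clinical table {path} is missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _CLINICAL_OPTIONAL:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = float(row[col]) if col == "age" else str(row[col])
        records.append(ClinicalRecord(
            sample_id=str(row["sample_id"]),
            os_time=float(row["os_time"]),
            os_event=int(row["os_event"]),
            **kwargs,
        ))
    return records


def clinical_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample_id."""
    rows = []
    for r in records:
        rows.append({"sample_id": r.sample_id, "os_time": r.os_time,
                     "os_event": r.os_event, "age": r.age, "sex": r.sex,
                     "stage": r.stage, "tissue_site": r.tissue_site,
                     "response": r.response, "subtype": r.subtype})
    return pd.DataFrame(rows).set_index("sample_id")


def write_clinical_table(records: list[ClinicalRecord], path: str | os.PathLike) -> None:
    clinical_to_frame(records).to_csv(path, sep="\t")


def chain_presence_matrix(repertoires: list[Repertoire],
                          samples: list[str]) -> pd.DataFrame:
    """Binary samples × chains matrix: 1 iff the sample has at least one
    assembled clone with positive count for that chain."""
    mat = pd.DataFrame(0, index=list(samples), columns=list(CHAINS), dtype=int)
    for rep in repertoires:
        if rep.sample_id in mat.index and any(c.count > 0 for c in rep.clones):
            mat.loc[rep.sample_id, rep.chain] = 1
    return mat
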