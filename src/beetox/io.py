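"""Plain-text readers/writers for every table the pipeline exchanges.

Counts and ground truth travel as TSV (genes in rows, header = sample ids or
treatment labels), metadata / survival / intake / results as CSV.  Floats are
serialised with a fixed ``%.6g`` format and LF newlines so that reruns with
identical seeds produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.6g"


def _write(df: pd.DataFrame, path, sep: str, index: bool) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_counts(counts: pd.DataFrame, path) -> None:
    _write(counts, path, sep="\t", index=True)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    df.columns.name = "sample_id"
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    _write(meta[["sample_id", "treatment", "compound", "scheme", "colony"]], path, ",", False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth(lfc: pd.DataFrame, category: pd.Series, path) -> None:
    out = lfc.copy()
    out.insert(0, "category", category)
    _write(out, path, sep="\t", index=True)


def read_truth(path) -> tuple[pd.DataFrame, pd.Series]:
    # keep_default_na: the category label "null" is data, not a missing value
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    category = df["category"]
    return df.drop(columns=["category"]).astype(float), category


def write_survival(records: pd.DataFrame, path) -> None:
    _write(records, path, ",", False)


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_intake(records: pd.DataFrame, path) -> None:
    _write(records, path, ",", False)


def read_intake(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_de_table(table: pd.DataFrame, path) -> None:
    _write(table.reset_index(drop=True), path, sep="\t", index=False)


def read_de_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene_id", drop=False).rename_axis(None)


def write_gene_list(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_list(path) -> list[str]:
    return [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
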