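"""Readers and writers for the text formats the pipeline speaks.

Genotypes use a GeneNetwork-style ``.geno`` dialect::

    @name:SIMPANEL
    @type:riset
    @mat:B
    @pat:A
    @het:H
    @unk:U
    Chr	Locus	cM	Mb	Strain1	Strain2	...
    1	m1_0000	0.0	0.000	A	B	...

Trait and assay tables are tab-separated with a one-line header; missing
values are empty fields.  Writers and readers round-trip bit-exactly on
valid inputs.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .panel import GENO_CODES, PanelError, RIPanel, TraitTable

__all__ = [
    "read_geno",
    "write_geno",
    "read_trait_table",
    "write_trait_table",
    "read_assay_table",
    "write_assay_table",
    "GenoFormatError",
]

PathLike = Union[str, Path]

GENO_FIXED_COLUMNS = ["Chr", "Locus", "cM", "Mb"]

ASSAY_COLUMNS = [
    "mouse_id",
    "strain_id",
    "assay",
    "test_binding",
    "normal_binding",
    "nonspecific_binding",
    "test_cAMP",
    "control_cAMP",
    "od_490",
    "value",
    "timepoint",
]


class GenoFormatError(PanelError):
    """Malformed .geno input; message carries the offending line number."""


def write_geno(panel: RIPanel, path: PathLike, name: str = "SIMPANEL",
               header_comment: Optional[str] = None) -> None:
    lines = []
    if header_comment:
        for raw in header_comment.splitlines():
            lines.append(f"#{raw}")
    lines += [
        f"@name:{name}",
        "@type:riset",
        "@mat:B",
        "@pat:A",
        "@het:H",
        "@unk:U",
        "\t".join(GENO_FIXED_COLUMNS + panel.strain_ids),
    ]
    mk = panel.markers
    for i in range(panel.n_markers):
        row = [
            str(mk["chromosome"].iat[i]),
            str(mk["marker"].iat[i]),
            repr(float(mk["position_cM"].iat[i])),
            repr(float(mk["position_Mb"].iat[i])),
        ] + list(panel.genotypes[i])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_geno(path: PathLike) -> RIPanel:
    text = Path(path).read_text()
    strain_ids: Optional[list[str]] = None
    rows = []
    codes = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#") or line.startswith("@"):
            continue
        fields = line.split("\t")
        if strain_ids is None:
            if fields[: len(GENO_FIXED_COLUMNS)] != GENO_FIXED_COLUMNS:
                raise GenoFormatError(
                    f"line {lineno}: header must start with "
                    f"{GENO_FIXED_COLUMNS}, got {fields[:4]}"
                )
            strain_ids = fields[len(GENO_FIXED_COLUMNS):]
            if not strain_ids:
                raise GenoFormatError(f"line {lineno}: no strain columns")
            continue
        if len(fields) != len(GENO_FIXED_COLUMNS) + len(strain_ids):
            raise GenoFormatError(
                f"line {lineno}: expected {len(GENO_FIXED_COLUMNS) + len(strain_ids)} "
                f"fields, got {len(fields)}"
            )
        chrom, locus, cm, mb = fields[:4]
        try:
            cm_f, mb_f = float(cm), float(mb)
        except ValueError as exc:
            raise GenoFormatError(f"line {lineno}: bad position ({exc})") from None
        strain_codes = fields[4:]
        for j, code in enumerate(strain_codes):
            if code not in GENO_CODES:
                raise GenoFormatError(
                    f"line {lineno}: invalid genotype code {code!r} for "
                    f"strain {strain_ids[j]!r}"
                )
        rows.append((locus, chrom, cm_f, mb_f))
        codes.append(strain_codes)
    if strain_ids is None:
        raise GenoFormatError("no header line found")
    if not rows:
        raise GenoFormatError("no marker lines found")
    markers = pd.DataFrame(
        rows, columns=["marker", "chromosome", "position_cM", "position_Mb"]
    )
    try:
        return RIPanel(strain_ids, markers, np.array(codes, dtype="<U1"))
    except PanelError as exc:
        raise GenoFormatError(str(exc)) from None


# -- trait tables -------------------------------------------------------

def write_trait_table(table: TraitTable, path: PathLike,
                      header_comment: Optional[str] = None) -> None:
    cols = ["strain_id", "trait", "mean", "sem", "n_mice", "sem_flagged"]
    _write_tsv(table.summary[cols], path, header_comment)


def read_trait_table(path: PathLike) -> TraitTable:
    df = _read_tsv(path)
    if "sem_flagged" in df.columns:
        df["sem_flagged"] = df["sem_flagged"].astype(bool)
    return TraitTable(summary=df)


# -- assay tables -------------------------------------------------------

def write_assay_table(records: pd.DataFrame, path: PathLike,
                      header_comment: Optional[str] = None) -> None:
    out = records.copy()
    for col in ASSAY_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    _write_tsv(out[ASSAY_COLUMNS], path, header_comment)


def read_assay_table(path: PathLike) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"mouse_id", "strain_id", "assay"} - set(df.columns)
    if missing:
        raise PanelError(f"assay table lacks columns: {sorted(missing)}")
    return df


# -- helpers ------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: PathLike,
               header_comment: Optional[str] = None) -> None:
    buf = io.StringIO()
    if header_comment:
        for raw in header_comment.splitlines():
            buf.write(f"#{raw}\n")
    df.to_csv(buf, sep="\t", index=False, na_rep="")
    Path(path).write_text(buf.getvalue())


def _read_tsv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", comment="#")
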