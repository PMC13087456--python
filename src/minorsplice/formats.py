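"""Readers and writers for the plain-text formats shared across stages.

Formats and conventions
-----------------------
* **VCF** — a deliberately minimal VCF 4.2 dialect: INFO keys ``GENE``,
  ``AF`` (per-alt, ``.`` when absent from the reference panel), ``CODING``
  (0/1) and ``ORIGIN`` (parental origin shared by all carriers of the site,
  ``unknown`` when mixed or unphased); FORMAT ``GT`` only. One alt per row
  (decomposed upstream). Coordinates are 1-based.
* **BED6** — 0-based half-open intron annotation; the name field packs
  ``gene|intron_index|class`` with class in {U2, U12, unknown}.
* **TSV matrices** — UTF-8, tab-separated, header row, first column is the
  row identifier, ``.`` is the missing-value sentinel.
* **Counts TSV** — rows are intron ids; columns come in pairs
  ``<sample>.retained`` / ``<sample>.spliced``.
* **GMT** — gene sets: name, description, then member genes, tab-separated;
  trailing empty tokens (a common dialect artefact) are dropped.

All writers are canonicalizing, so ``write ∘ read ∘ write`` is byte-wise
idempotent for every format.
"""

from __future__ import annotations

import csv
import io
import json
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .variants import VariantCall

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_gmt",
    "write_gmt",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_json_report",
    "read_json_report",
]

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Annotated gene symbol">
##INFO=<ID=AF,Number=1,Type=Float,Description="Population allele frequency; missing means absent from the reference panel">
##INFO=<ID=CODING,Number=1,Type=Integer,Description="1 if the gene is protein coding, else 0">
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="Parental origin shared by all carriers (maternal/paternal/unknown)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _format_af(af: float | None) -> str:
    return "." if af is None else repr(float(af))


def write_vcf(
    calls: Iterable[VariantCall],
    path: str | Path,
    samples: Sequence[str] | None = None,
) -> None:
    """Write per-sample variant calls as a multi-sample minimal VCF."""
    calls = list(calls)
    if samples is None:
        samples = sorted({c.sample_id for c in calls})
    else:
        samples = list(samples)
    sample_idx = {s: i for i, s in enumerate(samples)}

    sites: dict[tuple, dict] = {}
    for c in calls:
        key = (c.chromosome, c.position, c.ref, c.alt)
        site = sites.setdefault(
            key, {"gene": c.gene, "af": c.population_af, "coding": c.coding, "gts": {}, "origins": set()}
        )
        if site["gene"] != c.gene or site["af"] != c.population_af or site["coding"] != c.coding:
            raise ValueError(f"conflicting annotations for site {key}")
        if c.sample_id not in sample_idx:
            raise ValueError(f"sample {c.sample_id} not in sample list")
        site["gts"][c.sample_id] = "1/1" if c.genotype == "hom_alt" else "0/1"
        site["origins"].add(c.parental_origin)

    lines = [_VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    for key in sorted(sites):
        chrom, pos, ref, alt = key
        site = sites[key]
        origin = site["origins"].pop() if len(site["origins"]) == 1 else "unknown"
        info = (
            f"GENE={site['gene']};AF={_format_af(site['af'])};"
            f"CODING={int(site['coding'])};ORIGIN={origin}"
        )
        gts = "\t".join(site["gts"].get(s, "0/0") for s in samples)
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_vcf(path: str | Path) -> tuple[list[VariantCall], list[str]]:
    """Read the minimal VCF dialect; returns (calls, sample order)."""
    calls: list[VariantCall] = []
    samples: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                fields = line.split("\t")
                if len(fields) < 10 or fields[8] != "FORMAT":
                    raise ValueError(f"{path}:{lineno}: malformed #CHROM header")
                samples = fields[9:]
                continue
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise ValueError(f"{path}:{lineno}: expected {9 + len(samples)} fields, got {len(fields)}")
            chrom, pos, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValueError(f"{path}:{lineno}: multi-allelic rows are not supported; decompose first")
            info = dict(kv.split("=", 1) for kv in fields[7].split(";") if "=" in kv)
            try:
                gene = info["GENE"]
                af = None if info.get("AF", ".") == "." else float(info["AF"])
                coding = bool(int(info.get("CODING", "0")))
                origin = info.get("ORIGIN", "unknown")
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: bad INFO field: {exc}") from exc
            if fields[8].split(":")[0] != "GT":
                raise ValueError(f"{path}:{lineno}: FORMAT must start with GT")
            for sample, gt_field in zip(samples, fields[9:]):
                gt = gt_field.split(":")[0].replace("|", "/")
                if gt in ("0/0", "./."):
                    continue
                genotype = "hom_alt" if gt == "1/1" else "het"
                calls.append(
                    VariantCall(
                        sample_id=sample,
                        chromosome=chrom,
                        position=int(pos),
                        ref=ref,
                        alt=alt,
                        genotype=genotype,
                        gene=gene,
                        coding=coding,
                        population_af=af,
                        parental_origin=origin,  # type: ignore[arg-type]
                    )
                )
    return calls, samples


# --- BED6 intron annotation -------------------------------------------------

def write_bed(annotation: "pd.DataFrame", path: str | Path) -> None:
    """Write an intron annotation as BED6 (0-based half-open).

    Expects a DataFrame indexed by intron_id with columns
    ``gene, chromosome, start, end, spliceosome_class, intron_index``.
    The BED name field packs ``gene|intron_index|class``; score is 0 and
    strand '+' (strand is not modelled).
    """
    rows = []
    for intron_id, r in annotation.iterrows():
        name = f"{r['gene']}|{int(r['intron_index'])}|{r['spliceosome_class']}"
        rows.append((r["chromosome"], int(r["start"]), int(r["end"]), name))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, name in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t+\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED6 intron annotation into a DataFrame indexed by intron_id.

    The intron_id is reconstructed as ``<gene>_i<intron_index>``.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 fields, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
                gene, idx, cls = fields[3].split("|")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end must exceed start (half-open intervals)")
            if cls not in ("U2", "U12", "unknown"):
                raise ValueError(f"{path}:{lineno}: unknown spliceosome class {cls!r}")
            records.append(
                {
                    "intron_id": f"{gene}_i{int(idx)}",
                    "gene": gene,
                    "chromosome": fields[0],
                    "start": start,
                    "end": end,
                    "intron_index": int(idx),
                    "spliceosome_class": cls,
                }
            )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        raise ValueError(f"{path}: empty annotation")
    if df["intron_id"].duplicated().any():
        dup = df.loc[df["intron_id"].duplicated(), "intron_id"].iloc[0]
        raise ValueError(f"{path}: duplicate intron id {dup}")
    return df.set_index("intron_id")


# --- TSV matrices -----------------------------------------------------------

def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    """Write a DataFrame as a TSV matrix with '.' for missing values."""
    matrix.to_csv(path, sep="\t", na_rep=".", index_label=index_label, lineterminator="\n")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix; first column is the row identifier, '.' is missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."], keep_default_na=False)
    return df


def write_counts_tsv(retained: pd.DataFrame, spliced: pd.DataFrame, path: str | Path) -> None:
    """Write paired retained/spliced count matrices as one TSV.

    Both inputs are introns × samples with identical axes; output columns are
    ``<sample>.retained`` and ``<sample>.spliced``.
    """
    if not retained.index.equals(spliced.index) or not retained.columns.equals(spliced.columns):
        raise ValueError("retained and spliced matrices must share both axes")
    out = pd.DataFrame(index=retained.index)
    for s in retained.columns:
        out[f"{s}.retained"] = retained[s].astype(int)
        out[f"{s}.spliced"] = spliced[s].astype(int)
    out.to_csv(path, sep="\t", index_label="intron_id", lineterminator="\n")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a paired-count TSV; returns (retained, spliced), introns × samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = []
    for col in df.columns:
        if col.endswith(".retained"):
            sample = col[: -len(".retained")]
            if f"{sample}.spliced" not in df.columns:
                raise ValueError(f"{path}: column {col} lacks its .spliced pair")
            samples.append(sample)
        elif not col.endswith(".spliced"):
            raise ValueError(f"{path}: unexpected column {col}")
    retained = df[[f"{s}.retained" for s in samples]].astype(int)
    retained.columns = samples
    spliced = df[[f"{s}.spliced" for s in samples]].astype(int)
    spliced.columns = samples
    if (retained < 0).any().any() or (spliced < 0).any().any():
        raise ValueError(f"{path}: negative counts")
    return retained, spliced


# --- GMT gene sets ----------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs name and description")
            name = fields[0]
            genes = [g for g in fields[2:] if g]  # drop trailing empty tokens
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set {name}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, "na", *sets[name]]) + "\n")


# --- sample sheets & JSON ---------------------------------------------------

def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a sample sheet CSV: first column 'sample', remaining columns free-form."""
    df = pd.read_csv(path)
    if df.columns[0] != "sample":
        raise ValueError(f"{path}: first column must be 'sample', got {df.columns[0]!r}")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df.set_index("sample")


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, index_label="sample", lineterminator="\n")


def write_json_report(obj: object, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json_report(path: str | Path) -> object:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
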