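"""Readers and writers for genotype, read-bundle and metadata formats.

Supported genotype dialects:

* **Genepop** -- multi-allelic integer genotypes, 6-character (two 3-digit
  alleles) on write; both 6- and 4-character genotypes auto-detected on
  read.  ``000``/``00`` codes mean missing.  Population blocks are
  separated by ``Pop`` lines.  Population identifiers are encoded in
  individual labels as ``population:individual`` (plain labels fall back
  to ``pop1``, ``pop2``, ...).
* **minimal VCF 4.2** -- biallelic SNP loci only, GT format field.
* **TSV** -- ``individual``, ``population``, then one ``a1/a2`` column per
  locus; ``./.`` means missing.

Region labels and marker kinds are not carried by Genepop or VCF; callers
supply the marker kind on read (``marker_kind=`` argument) and regions via
the population-metadata table.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from .model import (
    MISSING,
    FragdivError,
    GenotypeMatrix,
    ParseError,
    PopulationMeta,
    ReadBundleSet,
    UnsupportedFormatError,
)

log = logging.getLogger("fragdiv")

_FORMATS = ("genepop", "vcf", "tsv")


def setup_logging(verbosity: int = 0) -> None:
    """Route package logging to standard error at the requested level."""
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


# ---------------------------------------------------------------------------
# dispatch


def read_genotypes(path: str | Path, format: str,
                   marker_kind: str = "ssr_length") -> GenotypeMatrix:
    """Read a genotype file in the named dialect.

    ``marker_kind`` labels the loci for dialects that do not carry marker
    kinds (Genepop, TSV); VCF loci are always ``snp``.
    """
    if format == "genepop":
        return _read_genepop(path, marker_kind)
    if format == "vcf":
        return _read_vcf(path)
    if format == "tsv":
        return _read_tsv(path, marker_kind)
    raise UnsupportedFormatError(f"unknown format {format!r}; choose from {_FORMATS}")


def write_genotypes(gm: GenotypeMatrix, path: str | Path, format: str) -> None:
    """Write a genotype matrix; output is re-readable by :func:`read_genotypes`."""
    if gm.n_individuals == 0 or gm.n_loci == 0:
        raise FragdivError("refusing to write an empty genotype matrix")
    if format == "genepop":
        _write_genepop(gm, path)
    elif format == "vcf":
        if any(k != "snp" for k in gm.marker_kinds):
            raise UnsupportedFormatError("ssr loci cannot be written to VCF")
        _write_vcf(gm, path)
    elif format == "tsv":
        _write_tsv(gm, path)
    else:
        raise UnsupportedFormatError(f"unknown format {format!r}; choose from {_FORMATS}")


# ---------------------------------------------------------------------------
# Genepop


def _split_pop_label(label: str, block_index: int) -> tuple[str, str]:
    if ":" in label:
        pop, ind = label.split(":", 1)
        return pop, ind
    return f"pop{block_index}", label


def _read_genepop(path: str | Path, marker_kind: str) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        row = lines[i].strip()
        if row:
            loci.extend(x.strip() for x in row.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise ParseError(f"{path}: malformed header, no 'Pop' line found")
    if not loci:
        raise ParseError(f"{path}: no locus names before first 'Pop'")

    individuals: list[str] = []
    populations: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    block = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        if not raw.strip():
            continue
        if raw.strip().lower() == "pop":
            block += 1
            continue
        if "," not in raw:
            raise ParseError(f"{path}:{lineno + 1}: expected 'label , genotypes'")
        label, geno_part = raw.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"{path}:{lineno + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        calls: list[tuple[int, int]] = []
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise ParseError(
                    f"{path}:{lineno + 1}: bad genotype token {tok!r} "
                    "(expected 4 or 6 digits)"
                )
            if width is None:
                width = len(tok) // 2
            elif len(tok) != 2 * width:
                raise ParseError(
                    f"{path}:{lineno + 1}: genotype width {len(tok)} "
                    f"inconsistent with detected width {2 * width}"
                )
            a, b = int(tok[:width]), int(tok[width:])
            if (a == 0) != (b == 0):
                raise ParseError(
                    f"{path}:{lineno + 1}: half-missing genotype {tok!r}"
                )
            calls.append((a, b))
        pop, ind = _split_pop_label(label.strip(), block)
        individuals.append(ind)
        populations[ind] = pop
        rows.append(calls)

    if not individuals:
        raise ParseError(f"{path}: no individual rows")
    raw_calls = np.array(rows, dtype=np.int64)  # (n, L, 2), 0 = missing
    calls = np.full_like(raw_calls, MISSING, dtype=np.int32)
    allele_labels: dict[str, list[str]] = {}
    w = width or 3
    for j, locus in enumerate(loci):
        col = raw_calls[:, j, :]
        codes = np.unique(col[col > 0])
        remap = {int(c): k for k, c in enumerate(codes)}
        allele_labels[locus] = [f"{int(c):0{w}d}" for c in codes]
        nz = col > 0
        calls[:, j, :][nz] = np.vectorize(remap.__getitem__, otypes=[np.int32])(col[nz]) if nz.any() else 0
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        regions={},
        loci=loci,
        marker_kinds=[marker_kind] * len(loci),
        calls=calls,
        allele_labels=allele_labels,
    )


def _write_genepop(gm: GenotypeMatrix, path: str | Path) -> None:
    out: list[str] = ["fragdiv genotypes"]
    out.extend(gm.loci)
    width = 3

    def code_str(locus: str, code: int) -> str:
        labels = gm.allele_labels.get(locus)
        if labels is not None and code < len(labels) and labels[code].isdigit():
            val = int(labels[code])
        else:
            val = code + 1
        if not 0 < val <= 999:
            raise UnsupportedFormatError(
                f"allele label {val} at {locus} does not fit 3-digit Genepop code"
            )
        return f"{val:0{width}d}"

    for pop in gm.population_ids():
        out.append("Pop")
        for row in gm.individuals_of(pop):
            ind = gm.individuals[row]
            toks = []
            for j, locus in enumerate(gm.loci):
                a, b = gm.calls[row, j]
                if a == MISSING:
                    toks.append("0" * (2 * width))
                else:
                    toks.append(code_str(locus, int(a)) + code_str(locus, int(b)))
            out.append(f"{pop}:{ind} , " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# VCF (minimal 4.2, GT only)


def _write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    header = [
        "##fileformat=VCFv4.2",
        "##source=fragdiv",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
    ]
    samples = [f"{gm.populations[ind]}:{ind}" for ind in gm.individuals]
    header.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(samples))
    body: list[str] = []
    for j, locus in enumerate(gm.loci):
        labels = gm.allele_labels.get(locus, ["A", "C"])
        ref = labels[0] if labels else "A"
        alt = labels[1] if len(labels) > 1 else "C"
        gts = []
        for i in range(gm.n_individuals):
            a, b = gm.calls[i, j]
            gts.append("./." if a == MISSING else f"{a}/{b}")
        body.append(f"1\t{j + 1}\t{locus}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts))
    Path(path).write_text("\n".join(header + body) + "\n")


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    samples: list[str] | None = None
    loci: list[str] = []
    labels: dict[str, list[str]] = {}
    rows: list[list[tuple[int, int]]] = []
    for lineno, raw in enumerate(lines, start=1):
        if raw.startswith("##") or not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if raw.startswith("#CHROM"):
            if len(fields) < 10:
                raise ParseError(f"{path}:{lineno}: VCF header has no samples")
            samples = fields[9:]
            continue
        if samples is None:
            raise ParseError(f"{path}:{lineno}: record before #CHROM header")
        if len(fields) != 9 + len(samples):
            raise ParseError(
                f"{path}:{lineno}: {len(fields)} columns, expected {9 + len(samples)}"
            )
        chrom, pos, vid, ref, alt, _qual, _filt, _info, fmt = fields[:9]
        if not fmt.split(":")[0] == "GT":
            raise ParseError(f"{path}:{lineno}: first FORMAT key must be GT")
        locus = vid if vid not in (".", "") else f"{chrom}_{pos}"
        loci.append(locus)
        labels[locus] = [ref] + ([alt] if alt not in (".", "") else [])
        calls: list[tuple[int, int]] = []
        for s in fields[9:]:
            gt = s.split(":")[0].replace("|", "/")
            if gt in (".", "./."):
                calls.append((MISSING, MISSING))
                continue
            try:
                a, b = (int(x) for x in gt.split("/"))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad GT field {gt!r}") from exc
            if not (0 <= a <= 1 and 0 <= b <= 1):
                raise ParseError(f"{path}:{lineno}: non-biallelic GT {gt!r}")
            calls.append((a, b))
        rows.append(calls)
    if samples is None:
        raise ParseError(f"{path}: no #CHROM header line")
    individuals: list[str] = []
    populations: dict[str, str] = {}
    for k, s in enumerate(samples):
        pop, ind = _split_pop_label(s, 1)
        individuals.append(ind)
        populations[ind] = pop
    calls_arr = (
        np.array(rows, dtype=np.int32).transpose(1, 0, 2)
        if rows
        else np.zeros((len(individuals), 0, 2), dtype=np.int32)
    )
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        regions={},
        loci=loci,
        marker_kinds=["snp"] * len(loci),
        calls=calls_arr,
        allele_labels=labels,
    )


# ---------------------------------------------------------------------------
# TSV genotype table


def _write_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    out = ["individual\tpopulation\t" + "\t".join(gm.loci)]
    for i, ind in enumerate(gm.individuals):
        toks = []
        for j in range(gm.n_loci):
            a, b = gm.calls[i, j]
            toks.append("./." if a == MISSING else f"{a}/{b}")
        out.append(f"{ind}\t{gm.populations[ind]}\t" + "\t".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


def _read_tsv(path: str | Path, marker_kind: str) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header[:2] != ["individual", "population"]:
        raise ParseError(f"{path}:1: header must start 'individual\\tpopulation'")
    loci = header[2:]
    individuals: list[str] = []
    populations: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != len(header):
            raise ParseError(
                f"{path}:{lineno}: {len(fields)} columns, expected {len(header)}"
            )
        ind, pop = fields[0], fields[1]
        individuals.append(ind)
        populations[ind] = pop
        calls: list[tuple[int, int]] = []
        for tok in fields[2:]:
            if tok in ("./.", "."):
                calls.append((MISSING, MISSING))
                continue
            try:
                a, b = (int(x) for x in tok.split("/"))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad genotype {tok!r}") from exc
            if a < 0 or b < 0:
                raise ParseError(f"{path}:{lineno}: negative allele code {tok!r}")
            calls.append((a, b))
        rows.append(calls)
    if not rows:
        raise ParseError(f"{path}: no genotype rows")
    return GenotypeMatrix(
        individuals=individuals,
        populations=populations,
        regions={},
        loci=loci,
        marker_kinds=[marker_kind] * len(loci),
        calls=np.array(rows, dtype=np.int32),
    )


# ---------------------------------------------------------------------------
# read bundles


def read_read_bundles(path: str | Path) -> ReadBundleSet:
    """Read a TSV of columns individual, locus, sequence, count."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    if header != ["individual", "locus", "sequence", "count"]:
        raise ParseError(f"{path}:1: expected header individual/locus/sequence/count")
    bundles = ReadBundleSet()
    valid = set("ACGTN")
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        ind, locus, seq, count_s = fields
        seq = seq.upper()
        if not seq or set(seq) - valid:
            raise ParseError(f"{path}:{lineno}: non-ACGTN sequence")
        try:
            count = int(count_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: bad count {count_s!r}") from exc
        if count < 1:
            raise ParseError(f"{path}:{lineno}: count must be >= 1")
        try:
            bundles.add(ind, locus, seq, count)
        except FragdivError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return bundles


def write_read_bundles(bundles: ReadBundleSet, path: str | Path) -> None:
    out = ["individual\tlocus\tsequence\tcount"]
    for (ind, locus), bundle in bundles.items():
        for seq, count in bundle.items():
            out.append(f"{ind}\t{locus}\t{seq}\t{count}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# population metadata


def read_population_meta(path: str | Path) -> list[PopulationMeta]:
    """Read a TSV of population, latitude, longitude, census_category,
    region and optional census_count columns."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split("\t")
    required = ["population", "latitude", "longitude", "census_category", "region"]
    for col in required:
        if col not in header:
            raise ParseError(f"{path}:1: missing column {col!r}")
    idx = {c: header.index(c) for c in header}
    metas: list[PopulationMeta] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        f = raw.split("\t")
        try:
            count = None
            if "census_count" in idx and f[idx["census_count"]] not in ("", "NA"):
                count = int(f[idx["census_count"]])
            metas.append(PopulationMeta(
                population=f[idx["population"]],
                latitude=float(f[idx["latitude"]]),
                longitude=float(f[idx["longitude"]]),
                census_category=f[idx["census_category"]],
                region=f[idx["region"]],
                census_count=count,
            ))
        except (ValueError, IndexError, FragdivError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return metas


def write_population_meta(metas: list[PopulationMeta], path: str | Path) -> None:
    out = ["population\tlatitude\tlongitude\tcensus_category\tregion\tcensus_count"]
    for m in metas:
        count = "" if m.census_count is None else str(m.census_count)
        out.append(f"{m.population}\t{m.latitude}\t{m.longitude}\t"
                   f"{m.census_category}\t{m.region}\t{count}")
    Path(path).write_text("\n".join(out) + "\n")
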