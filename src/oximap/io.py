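"""Readers and writers for the external formats the pipeline touches.

BED is native (0-based half-open).  GFF3 is converted to the internal
convention on read and back on write.  All writers emit deterministic,
sorted output so a fixed-seed run is byte-reproducible.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from oximap.core import (
    CGSite,
    ConfigError,
    ExpressionRecord,
    FragmentAlignment,
    GeneModel,
    GenomicInterval,
    ModCall,
    ParseError,
    Scaffold,
    ValidationError,
    WGBSCall,
)

# classification of RepeatMasker/Censor-style labels into TE classes
_CLASS_I_ORDERS = {"LTR", "LINE", "SINE", "DIRS", "PLE", "LARD", "TRIM"}
_CLASS_II_ORDERS = {"DNA", "TIR", "RC", "HELITRON", "MITE", "CRYPTON", "MAVERICK"}
_NON_TE_CLASSES = {
    "SIMPLE_REPEAT",
    "LOW_COMPLEXITY",
    "SATELLITE",
    "RRNA",
    "TRNA",
    "SNRNA",
    "SRPRNA",
    "ARTEFACT",
}


# ---------------------------------------------------------------------------
# scaffolds


def read_scaffolds(path: str | Path) -> list[Scaffold]:
    df = pd.read_csv(path, sep="\t")
    if not {"scaffold", "length"} <= set(df.columns):
        raise ParseError(f"{path}: expected headered TSV with columns scaffold, length")
    return [Scaffold(str(r.scaffold), int(r.length)) for r in df.itertuples()]


def write_scaffolds(path: str | Path, scaffolds: Sequence[Scaffold]) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tlength\n")
        for s in sorted(scaffolds, key=lambda x: x.id):
            fh.write(f"{s.id}\t{s.length}\n")


# ---------------------------------------------------------------------------
# BED intervals


def read_intervals(path: str | Path, format: str = "BED3") -> list[GenomicInterval]:
    """Read BED3/BED6 intervals, preserving file order.

    Malformed lines raise :class:`ParseError` naming the line number;
    empty (``end <= start``) intervals raise :class:`ValidationError`.
    """
    if format not in ("BED3", "BED6"):
        raise ConfigError(f"unsupported BED format {format!r}")
    ncol = 3 if format == "BED3" else 6
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncol:
                raise ParseError(f"{path}:{ln}: expected >={ncol} tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            strand = "."
            if format == "BED6":
                strand = fields[5]
                if strand == "−":  # tolerate typographic minus
                    strand = "-"
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{ln}: {exc}") from exc
    return out


def write_intervals(path: str | Path, intervals: Sequence[GenomicInterval], bed6: bool = False) -> None:
    ivs = sorted(intervals, key=lambda i: (i.scaffold, i.start, i.end))
    with open(path, "w") as fh:
        for k, iv in enumerate(ivs):
            if bed6:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\tiv{k}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# TE features (BED6 + class/order/family columns)

from oximap.core import TEFeature  # noqa: E402  (keeps the import block compact)


def read_te_bed(path: str | Path) -> list[TEFeature]:
    """BED6 with three extra columns: te_class, order, family."""
    out: list[TEFeature] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{ln}: expected >=6 fields")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]), f[5] if f[5] in "+-." else ".")
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            te_class = f[6] if len(f) > 6 else "unknown"
            order = f[7] if len(f) > 7 else "unknown"
            family = f[8] if len(f) > 8 else "unknown"
            out.append(TEFeature(f[3], iv, te_class, order, family))
    return out


def write_te_bed(path: str | Path, tes: Sequence[TEFeature]) -> None:
    rows = sorted(tes, key=lambda t: (t.location.scaffold, t.location.start, t.location.end, t.te_id))
    with open(path, "w") as fh:
        for t in rows:
            iv = t.location
            fh.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{t.te_id}\t0\t{iv.strand}"
                f"\t{t.te_class}\t{t.order}\t{t.family}\n"
            )


def classify_te_label(label: str) -> tuple[str, str, str]:
    """Map a RepeatMasker-style ``class/family`` label to (class, order, family)."""
    parts = label.split("/")
    order = parts[0]
    family = parts[1] if len(parts) > 1 else "unknown"
    up = order.upper()
    if up in _CLASS_I_ORDERS:
        te_class = "I"
    elif up in _CLASS_II_ORDERS:
        te_class = "II"
    elif up.startswith("UNKNOWN") or up == "UNSPECIFIED":
        te_class = "unknown"
    else:
        te_class = "other"
    return te_class, order, family


def read_repeatmasker_out(path: str | Path, te_only: bool = False) -> list[TEFeature]:
    """Convert a RepeatMasker ``.out`` table to TE features.

    Header lines are skipped.  Under ``te_only`` simple repeats, low
    complexity and satellite rows are dropped, keeping transposable
    elements proper (repeats-excluding-TEs are analysed separately).
    """
    out: list[TEFeature] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.lower().startswith(("sw", "score", "there were no")):
                continue
            f = line.split()
            if len(f) < 11:
                raise ParseError(f"{path}:{ln}: expected >=11 whitespace-separated fields")
            label = f[10]
            base = label.split("/")[0].upper().rstrip("?")
            if te_only and base in _NON_TE_CLASSES:
                continue
            try:
                start = int(f[5]) - 1  # RepeatMasker is 1-based closed
                end = int(f[6])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            strand = "+" if f[8] == "+" else "-"
            te_class, order, family = classify_te_label(label)
            out.append(
                TEFeature(f"{f[9]}_{ln}", GenomicInterval(f[4], start, end, strand), te_class, order, family)
            )
    return out


# ---------------------------------------------------------------------------
# gene models (GFF3)

_UTR5_TYPES = {"five_prime_UTR", "five_prime_utr", "5UTR"}
_UTR3_TYPES = {"three_prime_UTR", "three_prime_utr", "3UTR"}


def read_gene_models(path: str | Path, upstream_bp: int = 1000) -> list[GeneModel]:
    """Read gene/exon/UTR rows from GFF3 into gene models.

    GFF3 1-based closed coordinates are converted to 0-based half-open.
    Exons/UTRs are attached to their gene through ``Parent`` chains (an
    mRNA level is tolerated).  Orphan children produce a warning and are
    skipped; a duplicated gene ID is an error.
    """
    import gffutils

    # duplicate gene IDs must fail loudly before gffutils renames them
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#") or not raw.strip():
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) >= 9 and f[2] == "gene":
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                gid = attrs.get("ID", "")
                if gid in seen:
                    raise ValidationError(f"{path}: duplicated gene ID {gid!r}")
                seen.add(gid)

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        sort_attribute_values=True,
    )

    def gene_ancestor(feat) -> str | None:
        cur = feat
        for _ in range(4):  # bounded parent walk
            parents = list(db.parents(cur, level=1))
            if not parents:
                return None
            cur = parents[0]
            if cur.featuretype == "gene":
                return cur.id
        return None

    children: dict[str, dict[str, list[GenomicInterval]]] = {}
    for feat in db.all_features():
        if feat.featuretype == "exon":
            slot = "exons"
        elif feat.featuretype in _UTR5_TYPES:
            slot = "utr5"
        elif feat.featuretype in _UTR3_TYPES:
            slot = "utr3"
        else:
            continue
        gid = gene_ancestor(feat)
        if gid is None:
            warnings.warn(f"{path}: orphan {feat.featuretype} at {feat.seqid}:{feat.start}; skipped")
            continue
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand if feat.strand in "+-" else "+")
        children.setdefault(gid, {}).setdefault(slot, []).append(iv)

    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        body = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand if g.strand in "+-" else "+")
        kid = children.get(g.id, {})
        genes.append(
            GeneModel(
                g.id,
                body,
                exons=tuple(kid.get("exons", [])),
                utr5=tuple(kid.get("utr5", [])),
                utr3=tuple(kid.get("utr3", [])),
                upstream_bp=upstream_bp,
            )
        )
    genes.sort(key=lambda g: (g.body.scaffold, g.body.start, g.gene_id))
    return genes


def write_gene_models(path: str | Path, genes: Sequence[GeneModel]) -> None:
    """Write gene models as GFF3 (gene + exon + UTR rows)."""

    def row(iv: GenomicInterval, ftype: str, attrs: str) -> str:
        return (
            f"{iv.scaffold}\toximap\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
        )

    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.body.scaffold, x.body.start, x.gene_id)):
            fh.write(row(g.body, "gene", f"ID={g.gene_id}"))
            for k, ex in enumerate(g.exons):
                fh.write(row(ex, "exon", f"ID={g.gene_id}.exon{k};Parent={g.gene_id}"))
            for k, u in enumerate(g.utr5):
                fh.write(row(u, "five_prime_UTR", f"ID={g.gene_id}.utr5.{k};Parent={g.gene_id}"))
            for k, u in enumerate(g.utr3):
                fh.write(row(u, "three_prime_UTR", f"ID={g.gene_id}.utr3.{k};Parent={g.gene_id}"))


# ---------------------------------------------------------------------------
# modification calls (bedGraph-like TSV)


def read_modcalls(
    path: str | Path,
    mod: str,
    sample_id: str = "",
    multimap: bool = False,
) -> list[ModCall]:
    """Read a bedGraph-like table (scaffold, start, end, coverage).

    ``end`` may be ``start + 1`` (C position) or ``start + 2`` (CG span);
    both reduce to the plus-strand C position.
    """
    out: list[ModCall] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ParseError(f"{path}:{ln}: expected 4 fields")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if end - start not in (1, 2):
                raise ValidationError(f"{path}:{ln}: span must be 1 (C) or 2 (CG), got {end - start}")
            try:
                cov = int(f[3])
                if f[3].strip() != str(cov):  # reject "2.5", "3.0"
                    raise ValueError
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: coverage must be an integer, got {f[3]!r}") from exc
            if cov < 0:
                raise ValidationError(f"{path}:{ln}: negative coverage {cov}")
            out.append(ModCall(CGSite(f[0], start), mod, cov, sample_id, multimap))
    return out


def write_modcalls(path: str | Path, calls: Sequence[ModCall]) -> None:
    rows = sorted(calls, key=lambda c: (c.site.scaffold, c.site.pos))
    with open(path, "w") as fh:
        for c in rows:
            fh.write(f"{c.site.scaffold}\t{c.site.pos}\t{c.site.pos + 1}\t{c.coverage}\n")


# ---------------------------------------------------------------------------
# WGBS counts


def read_wgbs(path: str | Path) -> list[WGBSCall]:
    df = pd.read_csv(path, sep="\t")
    need = {"scaffold", "pos", "methylated", "total"}
    if not need <= set(df.columns):
        raise ParseError(f"{path}: expected headered TSV with columns {sorted(need)}")
    return [
        WGBSCall(CGSite(str(r.scaffold), int(r.pos)), int(r.methylated), int(r.total))
        for r in df.itertuples()
    ]


def write_wgbs(path: str | Path, calls: Sequence[WGBSCall]) -> None:
    rows = sorted(calls, key=lambda c: (c.site.scaffold, c.site.pos))
    with open(path, "w") as fh:
        fh.write("scaffold\tpos\tmethylated\ttotal\n")
        for c in rows:
            fh.write(f"{c.site.scaffold}\t{c.site.pos}\t{c.methylated}\t{c.total}\n")


# ---------------------------------------------------------------------------
# fragments (BED, optional name column = sample id)


def read_fragments(
    path: str | Path, sample_id: str = "", min_mapq: int | None = None
) -> list[FragmentAlignment]:
    """Read fragment intervals from BED (optional name and score columns).

    With ``min_mapq`` set, rows whose 5th (score) column is below the
    threshold are dropped; rows without a score column are kept (upstream
    mapping-quality filtering is assumed done).
    """
    out: list[FragmentAlignment] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 fields")
            try:
                left, right = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            if min_mapq is not None and len(f) > 4:
                try:
                    if float(f[4]) < min_mapq:
                        continue
                except ValueError as exc:
                    raise ParseError(f"{path}:{ln}: non-numeric score column") from exc
            sid = f[3] if len(f) > 3 and not sample_id else sample_id
            try:
                out.append(FragmentAlignment(f[0], left, right, sid))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{ln}: {exc}") from exc
    return out


def write_fragments(path: str | Path, frags: Sequence[FragmentAlignment]) -> None:
    rows = sorted(frags, key=lambda f: (f.scaffold, f.left, f.right, f.sample_id))
    with open(path, "w") as fh:
        for f in rows:
            fh.write(f"{f.scaffold}\t{f.left}\t{f.right}\t{f.sample_id}\n")


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "tpm"} <= set(df.columns):
        raise ParseError(f"{path}: expected headered TSV with columns gene_id, tpm")
    return [ExpressionRecord(str(r.gene_id), float(r.tpm)) for r in df.itertuples()]


def write_expression(path: str | Path, records: Sequence[ExpressionRecord]) -> None:
    rows = sorted(records, key=lambda r: r.gene_id)
    with open(path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for r in rows:
            fh.write(f"{r.gene_id}\t{r.tpm:.6g}\n")


# ---------------------------------------------------------------------------
# CG sites


def enumerate_cg_sites(
    sequence: str | None = None,
    fasta_path: str | Path | None = None,
    sites: Iterable[CGSite] | None = None,
    scaffold: str = "seq",
) -> list[CGSite]:
    """Enumerate CG dinucleotide positions (plus-strand C).

    Exactly one source must be supplied: a raw ``sequence`` (with a
    ``scaffold`` name), a ``fasta_path``, or an explicit ``sites`` list
    (validated, deduplicated and sorted).
    """
    supplied = sum(x is not None for x in (sequence, fasta_path, sites))
    if supplied != 1:
        raise ConfigError("supply exactly one of sequence, fasta_path or sites")
    if sites is not None:
        return sorted(set(sites))
    out: list[CGSite] = []
    if sequence is not None:
        out.extend(CGSite(scaffold, p) for p in _scan_cg(sequence))
    else:
        from pyfaidx import Fasta

        fa = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        for name in fa.keys():
            out.extend(CGSite(name, p) for p in _scan_cg(str(fa[name][:])))
    out.sort()
    return out


def _scan_cg(sequence: str) -> np.ndarray:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    if len(arr) < 2:
        return np.empty(0, dtype=np.int64)
    hit = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    return np.flatnonzero(hit).astype(np.int64)


def write_cg_sites(path: str | Path, sites: Sequence[CGSite]) -> None:
    rows = sorted(sites)
    with open(path, "w") as fh:
        for s in rows:
            fh.write(f"{s.scaffold}\t{s.pos}\t{s.pos + 1}\n")


def read_cg_sites(path: str | Path) -> list[CGSite]:
    return [CGSite(iv.scaffold, iv.start) for iv in read_intervals(path, "BED3")]


# ---------------------------------------------------------------------------
# window signal (bedGraph)


def write_bedgraph(path: str | Path, intervals: Sequence[GenomicInterval], values: Sequence[float]) -> None:
    if len(intervals) != len(values):
        raise ConfigError("intervals and values differ in length")
    order = sorted(range(len(intervals)), key=lambda i: (intervals[i].scaffold, intervals[i].start))
    with open(path, "w") as fh:
        for i in order:
            iv = intervals[i]
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{values[i]:.6g}\n")
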