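"""Readers and writers for the external formats.

GTF (via gffutils), expression/sample-sheet/mutation/domain TSVs, and
GMT gene sets.  GTF's 1-based closed coordinates are converted to the
package's 0-based half-open convention at parse time; MAF-style 1-based
mutation positions likewise.  All tabular writers prepend a provenance
header (``# key: value`` comment lines) that the readers skip.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .annotation import AnnotationError, GeneModel, TranscriptModel
from .enrichment import GeneSet
from .mutations import MUTATION_CLASSES, MutationTable
from .switching import AbundanceMatrix

logger = logging.getLogger("isoswitch")

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_domains",
    "attach_domains",
    "read_expression",
    "write_expression",
    "read_samples",
    "read_mutations",
    "write_mutations",
    "read_gmt",
    "write_gmt",
    "write_table",
]


# -- provenance -------------------------------------------------------------

def _header_lines(provenance: Mapping[str, object] | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_table(
    df: pd.DataFrame, path, provenance: Mapping[str, object] | None = None,
    index: bool = False,
) -> None:
    """Write a TSV with an optional ``# key: value`` provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance))
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# -- GTF --------------------------------------------------------------------

def read_gtf(path) -> list[GeneModel]:
    """Parse exon/CDS features of a GTF into gene models.

    Coordinates are converted from GTF's 1-based closed convention to
    0-based half-open.  ``gene_id`` and ``transcript_id`` attributes are
    mandatory on every exon/CDS feature.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("GTF %s is empty", path)
        return []
    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{path}: {feat.featuretype} feature at {feat.seqid}:{feat.start} "
                f"lacks attribute {exc}"
            ) from exc
        gname = feat.attributes.get("gene_name", [gid])[0]
        meta[tid] = (gid, feat.strand, gname)
        iv = (feat.start - 1, feat.end)  # to 0-based half-open
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    by_gene: dict[str, list[TranscriptModel]] = {}
    names: dict[str, str] = {}
    for tid, (gid, strand, gname) in meta.items():
        t = TranscriptModel(
            transcript_id=tid,
            gene_id=gid,
            strand=strand,
            exons=tuple(sorted(exons.get(tid, []))),
            cds=tuple(sorted(cds[tid])) if tid in cds else None,
        )
        by_gene.setdefault(gid, []).append(t)
        names[gid] = gname
    return [
        GeneModel(gid, names[gid], tuple(sorted(ts, key=lambda t: t.transcript_id)))
        for gid, ts in sorted(by_gene.items())
    ]


def write_gtf(genes: Iterable[GeneModel], path, spans=None) -> None:
    """Emit exon/CDS features (1-based closed), sorted deterministically."""
    spans = spans or {}
    with open(Path(path), "w") as fh:
        for g in genes:
            chrom = spans.get(g.gene_id, ("chr1",))[0]
            for t in g.transcripts:
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'gene_name "{g.gene_name}";'
                )
                for s, e in t.exons:
                    fh.write(
                        f"{chrom}\tisoswitch\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )
                for s, e in t.cds or ():
                    fh.write(
                        f"{chrom}\tisoswitch\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                    )


# -- domain side table ------------------------------------------------------

def read_domains(path) -> pd.DataFrame:
    df = _read_tsv(path)
    required = {"transcript_id", "domain_name", "start_aa", "end_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing columns: {sorted(missing)}")
    return df


def attach_domains(genes: list[GeneModel], domains: pd.DataFrame) -> list[GeneModel]:
    """Return gene models with domain annotations merged onto transcripts."""
    from dataclasses import replace

    by_tid: dict[str, set] = {}
    for row in domains.itertuples(index=False):
        by_tid.setdefault(row.transcript_id, set()).add(
            (row.domain_name, int(row.start_aa), int(row.end_aa))
        )
    out = []
    for g in genes:
        ts = tuple(
            replace(t, domains=frozenset(by_tid.get(t.transcript_id, set())))
            for t in g.transcripts
        )
        out.append(GeneModel(g.gene_id, g.gene_name, ts))
    return out


# -- expression -------------------------------------------------------------

def read_expression(path, samples: pd.DataFrame, tx2gene: pd.Series) -> AbundanceMatrix:
    """Read a transcript x sample abundance TSV and attach group labels.

    Matrix samples must all appear in the sample sheet; sheet samples
    absent from the matrix are dropped with a warning.  Negative or
    non-numeric cells are rejected.
    """
    df = _read_tsv(path, index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric abundance value in {path}: {exc}") from exc
    sheet_ids = set(samples["sample_id"])
    unknown = [c for c in df.columns if c not in sheet_ids]
    if unknown:
        raise ValueError(f"samples in matrix missing from sample sheet: {unknown[:5]}")
    extra = sheet_ids - set(df.columns)
    if extra:
        logger.warning("sample sheet entries absent from matrix dropped: %s",
                       sorted(extra))
    groups = samples.set_index("sample_id")["group"].loc[list(df.columns)]
    return AbundanceMatrix(df, tx2gene, groups)


def write_expression(m: AbundanceMatrix, path, provenance=None) -> None:
    df = m.values.rename_axis("transcript_id")
    write_table(df, path, provenance, index=True)


def read_samples(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype=str)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return df


# -- mutations --------------------------------------------------------------

def read_mutations(path) -> MutationTable:
    """Read a MAF-like mutation TSV (1-based positions converted to 0-based)."""
    df = _read_tsv(path, dtype={"sample_id": str, "gene_id": str})
    missing = {"sample_id", "gene_id", "mut_class"} - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    bad = set(df["mut_class"]) - MUTATION_CLASSES
    if bad:
        raise ValueError(
            f"unknown mutation class(es) {sorted(bad)}; allowed: "
            f"{sorted(MUTATION_CLASSES)}"
        )
    if "pos" in df.columns:
        df = df.assign(pos=df["pos"].astype(int) - 1)
    if "transcript_id" in df.columns:
        df["transcript_id"] = df["transcript_id"].fillna("")
    return MutationTable(df)


def write_mutations(muts: MutationTable, path, provenance=None) -> None:
    df = muts.records.copy()
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(int) + 1  # back to 1-based MAF convention
    write_table(df, path, provenance)


# -- GMT --------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(Path(path), "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")
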