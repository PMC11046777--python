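"""Format readers and writers shared by the build and classify stages."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

from Bio import SeqIO

from .taxonomy import TaxonomyTree, rank_code

logger = logging.getLogger(__name__)

CLASSIFICATION_COLUMNS = (
    "readID",
    "seqID",
    "taxID",
    "score",
    "2ndBestScore",
    "hitLength",
    "queryLength",
    "numMatches",
)


def _open_text(path):
    path = Path(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def sniff_fastx_format(path) -> str:
    with _open_text(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            raise ValueError(f"{path}: empty sequence file")
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: not FASTA or FASTQ (first character {first!r})")


def read_fastx(path):
    """Yield (id, uppercase sequence, qualities or None) records.

    FASTA/FASTQ, plain or gzip, auto-detected. Malformed records raise
    ValueError with the offending file named.
    """
    fmt = sniff_fastx_format(path)
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, fmt):
                qual = None
                if fmt == "fastq":
                    qual = "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    )
                yield rec.id, str(rec.seq).upper(), qual
        except ValueError as exc:
            raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc


def read_seqid_map(path) -> dict[str, int]:
    """Two-column TSV mapping sequence IDs to taxonomy IDs."""
    mapping: dict[str, int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            try:
                mapping[parts[0]] = int(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: taxonomy ID must be an integer") from None
    return mapping


def write_classification(results, path) -> int:
    """One TSV row per read (Centrifuge-style columns); returns row count."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(CLASSIFICATION_COLUMNS) + "\n")
        for res in results:
            if not res.classified:
                fh.write(
                    f"{res.read_id}\tunclassified\t0\t0\t0\t0\t{res.query_length}\t0\n"
                )
            else:
                for label, taxid, score in res.assignments:
                    fh.write(
                        f"{res.read_id}\t{label}\t{taxid}\t{score}\t"
                        f"{res.second_best_score}\t{res.hit_length}\t"
                        f"{res.query_length}\t{res.n_assignments}\n"
                    )
            n += 1
    return n


def kraken_report_rows(results, tree: TaxonomyTree):
    """Aggregate per-read assignments into Kraken-style report rows.

    Each row is (percent, clade_count, direct_count, rank_code, taxid,
    indented name); clade counts are direct counts summed over subtrees,
    rows appear in depth-first order, and an unclassified row leads when
    applicable.
    """
    direct: dict[int, int] = {}
    unclassified = 0
    total = 0
    for res in results:
        total += 1
        if not res.classified:
            unclassified += 1
            continue
        taxid = res.assignments[0][1]
        if taxid not in tree:
            taxid = tree.root
        direct[taxid] = direct.get(taxid, 0) + 1
    kids = tree.children_map()
    clade: dict[int, int] = {}

    def fill(t: int) -> int:
        c = direct.get(t, 0) + sum(fill(k) for k in kids[t])
        clade[t] = c
        return c

    fill(tree.root)
    rows = []
    if unclassified:
        pct = 100.0 * unclassified / total if total else 0.0
        rows.append((pct, unclassified, unclassified, "U", 0, "unclassified"))

    def walk(t: int, depth: int):
        if clade[t] == 0:
            return
        pct = 100.0 * clade[t] / total if total else 0.0
        code = rank_code(tree.rank(t), root=(t == tree.root))
        rows.append((pct, clade[t], direct.get(t, 0), code, t, "  " * depth + tree.name(t)))
        for k in kids[t]:
            walk(k, depth + 1)

    walk(tree.root, 0)
    return rows


def write_kraken_report(results, tree: TaxonomyTree, path) -> None:
    rows = kraken_report_rows(results, tree)
    with open(path, "w") as fh:
        for pct, clade_n, direct_n, code, taxid, name in rows:
            fh.write(f"{pct:.2f}\t{clade_n}\t{direct_n}\t{code}\t{taxid}\t{name}\n")
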