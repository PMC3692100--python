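"""Reading and writing phyletic patterns, annotations and network files.

A phyletic pattern (phylogenetic profile) is a strict 0/1 matrix — rows are
species, columns are binary characters such as gene families, restriction
sites, introns or indels.  It is equivalent to a gap-free alignment over the
alphabet {0, 1}, so the FASTA dialect here simply writes each taxon's row as
a 0/1 "sequence".  Missing data is deliberately rejected: silently imputing
'?' cells would change every downstream likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PhyleticPattern",
    "AnnotationTable",
    "PatternError",
    "read_pattern",
    "write_pattern",
    "read_annotations",
    "export_network",
]

logger = logging.getLogger(__name__)

FASTA_WRAP = 60


class PatternError(ValueError):
    """Raised for malformed phyletic-pattern input."""


@dataclass
class PhyleticPattern:
    """Taxa-by-characters 0/1 matrix with optional character annotations.

    Attributes
    ----------
    taxa : list of str
        Species names, one per matrix row; unique and non-empty.
    characters : list of str
        Character identifiers, one per column; unique.
    matrix : ndarray of uint8, shape (n_taxa, n_characters)
        Presence (1) / absence (0) states.
    annotations : dict or None
        Optional free-text description per character id.
    """

    taxa: list
    characters: list
    matrix: np.ndarray
    annotations: dict | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise PatternError("matrix must be two-dimensional")
        if len(self.taxa) != self.matrix.shape[0]:
            raise PatternError("row count must equal number of taxa")
        if len(self.characters) != self.matrix.shape[1]:
            raise PatternError("column count must equal number of characters")
        if len(self.characters) == 0:
            raise PatternError("no characters")
        if any(not t for t in self.taxa):
            raise PatternError("taxon names must be non-empty")
        if len(set(self.taxa)) != len(self.taxa):
            raise PatternError("duplicate taxon name")
        if len(set(self.characters)) != len(self.characters):
            raise PatternError("duplicate character id")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise PatternError("binary characters only: matrix entries must be 0 or 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def column(self, character_id: str) -> np.ndarray:
        return self.matrix[:, self.characters.index(character_id)]

    def __eq__(self, other) -> bool:
        return (isinstance(other, PhyleticPattern)
                and self.taxa == other.taxa
                and self.characters == other.characters
                and np.array_equal(self.matrix, other.matrix))


@dataclass
class AnnotationTable:
    """Map from character id to a free-text description."""

    entries: dict = field(default_factory=dict)

    def get(self, character_id, default=""):
        return self.entries.get(character_id, default)

    def check_against(self, pattern: PhyleticPattern) -> None:
        extra = set(self.entries) - set(pattern.characters)
        if extra:
            warnings.warn(
                f"{len(extra)} annotation ids are not in the pattern "
                f"(e.g. {sorted(extra)[0]!r})", UserWarning, stacklevel=2)


def _default_character_ids(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"C{i + 1:0{width}d}" for i in range(n)]


def read_pattern(path, format: str = "fasta01", transpose: bool = False) -> PhyleticPattern:
    """Read a phyletic pattern from FASTA-of-0/1 or TSV.

    In ``fasta01`` each record is one taxon and its sequence is that taxon's
    0/1 row (any line wrapping accepted); character ids are autogenerated
    C0001, C0002, ...  In ``tsv`` the header row holds character ids and the
    first column taxon names.  ``transpose`` flips a TSV written with
    rows=characters.  Any symbol outside {0, 1} is a fatal error.
    """
    if format == "fasta01":
        return _read_fasta01(path)
    if format == "tsv":
        return _read_tsv(path, transpose=transpose)
    raise PatternError(f"unknown pattern format: {format!r}")


def _read_fasta01(path) -> PhyleticPattern:
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    name = None
    chunks: list[str] = []

    def flush():
        if name is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise PatternError(f"empty sequence for taxon {name!r}")
        for pos, ch in enumerate(seq, start=1):
            if ch not in "01":
                raise PatternError(
                    f"binary characters only: taxon {name!r} has symbol "
                    f"{ch!r} at position {pos}")
        taxa.append(name)
        rows.append(np.frombuffer(seq.encode(), dtype=np.uint8) - ord("0"))

    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                chunks = []
            else:
                if name is None:
                    raise PatternError("sequence data before first FASTA header")
                chunks.append(line)
        flush()
    if not taxa:
        raise PatternError("no FASTA records found")
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise PatternError("ragged rows: sequences differ in length")
    matrix = np.vstack(rows)
    return PhyleticPattern(taxa=taxa,
                           characters=_default_character_ids(matrix.shape[1]),
                           matrix=matrix)


def _read_tsv(path, transpose: bool = False) -> PhyleticPattern:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if transpose:
        df = df.T
    if df.isna().any().any():
        raise PatternError("ragged rows: missing cells in TSV matrix")
    bad = ~df.isin(["0", "1"])
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise PatternError(
            f"binary characters only: taxon {df.index[r]!r}, character "
            f"{df.columns[c]!r} holds {df.values[r, c]!r}")
    return PhyleticPattern(taxa=[str(t) for t in df.index],
                           characters=[str(c) for c in df.columns],
                           matrix=df.values.astype(np.uint8))


def write_pattern(pattern: PhyleticPattern, path, format: str = "fasta01") -> None:
    """Write a pattern so that :func:`read_pattern` round-trips the matrix."""
    if pattern.n_characters == 0:
        raise PatternError("no characters")
    if format == "fasta01":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for taxon, row in zip(pattern.taxa, pattern.matrix):
                fh.write(f">{taxon}\n")
                seq = "".join("1" if v else "0" for v in row)
                for i in range(0, len(seq), FASTA_WRAP):
                    fh.write(seq[i:i + FASTA_WRAP] + "\n")
    elif format == "tsv":
        df = pd.DataFrame(pattern.matrix, index=pattern.taxa,
                          columns=pattern.characters)
        df.to_csv(path, sep="\t", index_label="taxon", lineterminator="\n")
    else:
        raise PatternError(f"unknown pattern format: {format!r}")


def read_annotations(path) -> AnnotationTable:
    """Read a two-column (id, description) TSV of character annotations.

    Malformed lines are skipped with a warning; on a duplicated id the first
    description wins and a warning is emitted.
    """
    entries: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t", 1)
            if len(parts) != 2 or not parts[0].strip():
                warnings.warn(f"skipping malformed annotation line {lineno}",
                              UserWarning, stacklevel=2)
                continue
            cid, desc = parts[0].strip(), parts[1].strip()
            if cid in entries:
                warnings.warn(f"duplicate annotation id {cid!r}: keeping first",
                              UserWarning, stacklevel=2)
                continue
            entries[cid] = desc
    return AnnotationTable(entries=entries)


def export_network(net, path, format: str = "tsv") -> None:
    """Write a coevolution network as SIF, GraphML or an edge-list TSV.

    SIF lines read ``id1 coevolves id2`` (Cytoscape-compatible); GraphML
    carries score/pvalue/qvalue as edge attributes and the annotation as a
    node attribute; TSV has columns id1, id2, score, pvalue, qvalue.
    """
    graph = net.graph if hasattr(net, "graph") else net
    if format == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for a, b in sorted(graph.edges()):
                fh.write(f"{a}\tcoevolves\t{b}\n")
    elif format == "graphml":
        nx.write_graphml(graph, path)
    elif format == "tsv":
        rows = [{"id1": a, "id2": b,
                 "score": data.get("score", np.nan),
                 "pvalue": data.get("pvalue", np.nan),
                 "qvalue": data.get("qvalue", np.nan)}
                for a, b, data in sorted(graph.edges(data=True))]
        df = pd.DataFrame(rows, columns=["id1", "id2", "score", "pvalue", "qvalue"])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g",
                  lineterminator="\n")
    else:
        raise PatternError(f"unknown network format: {format!r}")
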