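"""Edge-list reading/writing and delimited score/report output.

The only mandatory on-disk format is a two-column whitespace- or
tab-delimited edge list with ``#`` comments; node labels stay strings and
are never coerced to integers.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from .evaluation import ExperimentReport
from .graph import Graph, build_graph

logger = logging.getLogger("dicn")

LabelPair = tuple[str, str]


class EdgeListParseError(ValueError):
    """A malformed line in an edge-list file (carries the line number)."""


def read_edge_list(path: str | Path) -> tuple[list[LabelPair], list[str]]:
    """Parse an edge-list file into (edges, node labels in first-seen order).

    Lines starting with ``#`` and blank lines are ignored.  A line with a
    token count other than two is a parse error naming the line number; a
    file with no edges is an error.
    """
    path = Path(path)
    edges: list[LabelPair] = []
    labels: list[str] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 tokens, got {len(tokens)}"
                )
            u, v = tokens
            edges.append((u, v))
            for lab in (u, v):
                if lab not in seen:
                    seen.add(lab)
                    labels.append(lab)
    if not edges:
        raise EdgeListParseError(f"{path}: no edges found")
    return edges, labels


def read_graph(path: str | Path) -> Graph:
    """Read an edge-list file straight into a :class:`Graph`."""
    edges, labels = read_edge_list(path)
    return build_graph(edges, nodes=labels)


def write_edge_list(path: str | Path, g: Graph) -> None:
    """Write a graph as a two-column tab-delimited edge list."""
    with Path(path).open("w") as fh:
        for i, j in g.edges():
            fh.write(f"{g.labels[i]}\t{g.labels[j]}\n")


def write_scores(
    path: str | Path, records: Iterable[tuple[str, str, float]]
) -> None:
    """Write scored pairs as a three-column TSV, best score first.

    Rows are sorted by score descending, then lexicographically by the
    (sorted) label pair; scores print with 6 decimal places.
    """
    rows = []
    for u, v, s in records:
        a, b = sorted((str(u), str(v)))
        rows.append((a, b, float(s)))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with Path(path).open("w") as fh:
        fh.write("node_u\tnode_v\tscore\n")
        for a, b, s in rows:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def write_report(path: str | Path, reports: Sequence[ExperimentReport]) -> None:
    """Write evaluation reports as TSV: one row per repetition plus a
    summary row per report."""
    with Path(path).open("w") as fh:
        fh.write("method\tbeta\trepetition\tn\tn1\tn2\tauc\n")
        for rep in reports:
            for r, res in enumerate(rep.results):
                if res is None:
                    fh.write(f"{rep.method}\t{rep.beta:g}\t{r}\tNA\tNA\tNA\tNA\n")
                else:
                    fh.write(
                        f"{rep.method}\t{rep.beta:g}\t{r}\t{res.n}\t{res.n1}\t"
                        f"{res.n2}\t{res.auc:.6f}\n"
                    )
            fh.write(
                f"{rep.method}\t{rep.beta:g}\tmean\t\t\t\t{rep.mean_auc:.6f}\n"
            )
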