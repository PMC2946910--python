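"""Plain-text file dialects: expression matrices, ranked edge lists,
gold standards, and regulator lists.

Expression matrices are tab-separated with a header row of gene names and one
row per condition. Ranked edge lists and gold standards use the three-column
``regulator TAB target TAB value`` layout of the DREAM challenges.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .data import ExpressionMatrix
from .evaluation import GoldStandard
from .exceptions import ParseError
from .network import LinkRanking

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_link_ranking",
    "write_link_ranking",
    "read_gold_standard",
    "write_gold_standard",
    "read_gene_list",
]


def _lines(path):
    text = Path(path).read_text()
    for number, raw in enumerate(text.splitlines(), start=1):
        if raw.strip():
            yield number, raw


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix (header = gene names)."""
    rows = list(_lines(path))
    if len(rows) < 3:
        raise ParseError(f"{path}: need a header plus at least 2 condition rows")
    header_no, header = rows[0]
    gene_names = header.rstrip("\n").split("\t")
    gene_names = [g.strip() for g in gene_names]
    if len(set(gene_names)) != len(gene_names):
        raise ParseError(f"{path}:{header_no}: duplicate gene names in header")
    p = len(gene_names)
    values = []
    for number, raw in rows[1:]:
        cells = raw.split("\t")
        if len(cells) != p:
            raise ParseError(
                f"{path}:{number}: expected {p} columns, found {len(cells)}"
            )
        try:
            values.append([float(c) for c in cells])
        except ValueError:
            raise ParseError(f"{path}:{number}: non-numeric expression value") from None
    return ExpressionMatrix.from_array(np.asarray(values), gene_names=gene_names)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(matrix.gene_names) + "\n")
        for row in matrix.values:
            fh.write("\t".join(f"{v:.15g}" for v in row) + "\n")


def write_link_ranking(ranking: LinkRanking, path, max_links: int | None = None) -> None:
    """Write ``regulator TAB target TAB weight`` lines in ranking order."""
    n = len(ranking) if max_links is None else min(max_links, len(ranking))
    with open(path, "w") as fh:
        for i, (reg, tgt, w) in enumerate(ranking):
            if i >= n:
                break
            fh.write(f"{reg}\t{tgt}\t{w:.10e}\n")


def read_link_ranking(path, gene_names=None) -> LinkRanking:
    """Read a ranked edge list, trusting the file order (ties included).

    When ``gene_names`` is not given, the universe is the set of names seen in
    the file, in order of first appearance.
    """
    triples = []
    for number, raw in _lines(path):
        cells = raw.split("\t")
        if len(cells) != 3:
            raise ParseError(f"{path}:{number}: expected 3 tab-separated columns")
        reg, tgt, w = cells[0].strip(), cells[1].strip(), cells[2]
        try:
            w = float(w)
        except ValueError:
            raise ParseError(f"{path}:{number}: non-numeric weight") from None
        if reg == tgt:
            raise ParseError(f"{path}:{number}: self-link {reg!r}")
        triples.append((reg, tgt, w))
    if gene_names is None:
        seen = dict()
        for reg, tgt, _ in triples:
            seen.setdefault(reg, None)
            seen.setdefault(tgt, None)
        gene_names = tuple(seen)
    try:
        return LinkRanking.from_pairs(gene_names, triples, resort=False)
    except KeyError as exc:
        raise ParseError(f"{path}: gene {exc.args[0]!r} outside given universe") from None


def read_gold_standard(path, gene_names=None, candidate_regulators=None) -> GoldStandard:
    """Read ``regulator TAB target TAB {0|1}`` lines.

    1-labelled pairs are positives. If any 0-labelled pair is present, the
    0-labelled pairs define the explicit negative universe; otherwise the
    negatives are every candidate ordered pair that is not a positive.
    """
    positives, negatives = set(), set()
    names_seen = dict()
    for number, raw in _lines(path):
        cells = raw.split("\t")
        if len(cells) != 3:
            raise ParseError(f"{path}:{number}: expected 3 tab-separated columns")
        reg, tgt, label = cells[0].strip(), cells[1].strip(), cells[2].strip()
        if reg == tgt:
            raise ParseError(f"{path}:{number}: self-pair {reg!r}")
        if label not in ("0", "1"):
            raise ParseError(f"{path}:{number}: label must be 0 or 1, got {label!r}")
        names_seen.setdefault(reg, None)
        names_seen.setdefault(tgt, None)
        (positives if label == "1" else negatives).add((reg, tgt))
    if gene_names is None:
        gene_names = tuple(names_seen)
    return GoldStandard(
        gene_names=tuple(gene_names),
        positives=frozenset(positives),
        candidate_regulators=(
            tuple(candidate_regulators) if candidate_regulators else None
        ),
        explicit_negatives=frozenset(negatives) if negatives else None,
    )


def write_gold_standard(gold: GoldStandard, path) -> None:
    gene_order = {g: i for i, g in enumerate(gold.gene_names)}
    with open(path, "w") as fh:
        for r, t in sorted(gold.positives, key=lambda p: (gene_order[p[0]], gene_order[p[1]])):
            fh.write(f"{r}\t{t}\t1\n")
        if gold.explicit_negatives is not None:
            for r, t in sorted(
                gold.explicit_negatives, key=lambda p: (gene_order[p[0]], gene_order[p[1]])
            ):
                fh.write(f"{r}\t{t}\t0\n")


def read_gene_list(path) -> list:
    """One gene name per line (used for candidate-regulator lists)."""
    return [raw.strip() for _, raw in _lines(path)]
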