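"""Consistency-based alignment column filtering (heads-or-tails support).

Alternative alignments of the same sequences — e.g. several aligners run on
the forward and reversed sequences — vote on the reliability of each
consensus column: a residue pair is *supported* by an alternative when that
alignment also places the two residues in one column.  Columns containing a
residue pair observed in at most one underlying alignment are unreliable
and can be removed (strict mode); fraction mode instead thresholds the mean
pair support.

Only residue–residue pairs vote; gaps carry no information.  The consensus
does not vote for itself, so a consensus-only pair has raw support 0 (it is
treated like a singleton observation in strict mode).
"""

from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .treeio import GAP, Alignment

STRICT = "strict"
FRACTION = "fraction"


@dataclass
class ColumnReport:
    """Support summary for one consensus column (0-based index)."""

    column: int
    n_pairs: int
    support_histogram: dict[int, int]
    mean_support: float
    min_support: int
    kept: bool | None = None


def reverse_alignment(aln: Alignment) -> Alignment:
    """Reverse every row (column c maps to ncol-1-c); an involution."""
    return Alignment(list(aln.ids), [s[::-1] for s in aln.seqs])


def _pair_set(aln: Alignment) -> set[tuple]:
    """All residue pairs co-aligned in some column, canonically ordered."""
    indices = [aln.residue_index(r) for r in range(aln.nrow)]
    pairs: set[tuple] = set()
    for c in range(aln.ncol):
        present = [
            (aln.ids[r], indices[r][c])
            for r in range(aln.nrow)
            if indices[r][c] is not None
        ]
        for (ia, pa), (ib, pb) in itertools.combinations(present, 2):
            if ib < ia:
                (ia, pa), (ib, pb) = (ib, pb), (ia, pa)
            pairs.add((ia, pa, ib, pb))
    return pairs


def _validate_bundle(consensus: Alignment, alternatives: list[Alignment]) -> None:
    if len(alternatives) < 2:
        raise ValueError("need at least 2 alternative alignments (K >= 2)")
    ref = {
        consensus.ids[r]: consensus.ungapped(r) for r in range(consensus.nrow)
    }
    for k, alt in enumerate(alternatives):
        seqs = {alt.ids[r]: alt.ungapped(r) for r in range(alt.nrow)}
        if set(seqs) != set(ref):
            extra = set(seqs) ^ set(ref)
            raise ValueError(
                f"alternative #{k} has a different sequence set: {sorted(extra)}"
            )
        for seq_id, seq in ref.items():
            if seqs[seq_id] != seq:
                raise ValueError(
                    f"ungapped sequence mismatch for {seq_id!r} in "
                    f"alternative #{k}; reversed alignments must be "
                    "re-reversed before scoring"
                )


def column_pair_support(
    consensus: Alignment, alternatives: list[Alignment]
) -> list[ColumnReport]:
    """Score every consensus column by residue-pair support across alternatives.

    For each pair of residues sharing a consensus column, support is the
    number of alternatives also co-aligning them (0..K).  Columns with
    fewer than two residues have no pairs; their mean support is defined
    as 1.0 and their min support as K.
    """
    _validate_bundle(consensus, alternatives)
    K = len(alternatives)
    alt_sets = [_pair_set(alt) for alt in alternatives]
    indices = [consensus.residue_index(r) for r in range(consensus.nrow)]

    reports = []
    for c in range(consensus.ncol):
        present = [
            (consensus.ids[r], indices[r][c])
            for r in range(consensus.nrow)
            if indices[r][c] is not None
        ]
        supports = []
        for (ia, pa), (ib, pb) in itertools.combinations(present, 2):
            if ib < ia:
                (ia, pa), (ib, pb) = (ib, pb), (ia, pa)
            key = (ia, pa, ib, pb)
            supports.append(sum(key in s for s in alt_sets))
        n_pairs = len(supports)
        if n_pairs:
            mean = sum(supports) / (n_pairs * K)
            min_support = max(1, min(supports))
        else:
            mean = 1.0
            min_support = K
        reports.append(
            ColumnReport(
                column=c,
                n_pairs=n_pairs,
                support_histogram=dict(Counter(supports)),
                mean_support=mean,
                min_support=min_support,
            )
        )
    return reports


def filter_columns(
    consensus: Alignment,
    alternatives: list[Alignment],
    mode: str = STRICT,
    min_fraction: float = 0.5,
) -> tuple[Alignment, list[int]]:
    """Remove unreliable consensus columns by cross-alignment support.

    ``strict`` drops every column containing a residue pair observed in at
    most one underlying alignment; ``fraction`` drops columns whose mean
    pair support falls below ``min_fraction``.  Returns the filtered
    alignment (row order and residues untouched) and the kept column
    indices, strictly increasing.
    """
    if mode not in (STRICT, FRACTION):
        raise ValueError(f"unknown mode {mode!r}")
    reports = column_pair_support(consensus, alternatives)
    kept: list[int] = []
    for rep in reports:
        if mode == STRICT:
            keep = rep.n_pairs == 0 or rep.min_support > 1
        else:
            keep = rep.mean_support >= min_fraction
        rep.kept = keep
        if keep:
            kept.append(rep.column)
    if not kept:
        warnings.warn("all columns were filtered out; returning empty alignment")
    return consensus.select_columns(kept), kept


def restrict_to_residues(
    aln: Alignment, keep: dict[str, set[int]]
) -> Alignment:
    """Project an alignment onto a per-sequence subset of residue positions.

    Residues outside ``keep`` become gaps, all-gap columns are dropped, and
    surviving residues are implicitly renumbered.  Used to re-project
    alternative alignments onto the columns kept by :func:`filter_columns`.
    """
    rows = []
    for r in range(aln.nrow):
        idx = aln.residue_index(r)
        allowed = keep.get(aln.ids[r], set())
        rows.append(
            "".join(
                ch if idx[c] is not None and idx[c] in allowed else GAP
                for c, ch in enumerate(aln.seqs[r])
            )
        )
    non_empty = [
        c for c in range(aln.ncol) if any(row[c] != GAP for row in rows)
    ]
    return Alignment(list(aln.ids), ["".join(row[c] for c in non_empty) for row in rows])


def kept_residues(consensus: Alignment, kept_columns: list[int]) -> dict[str, set[int]]:
    """Residue positions of each sequence surviving a column filter."""
    out: dict[str, set[int]] = {}
    for r in range(consensus.nrow):
        idx = consensus.residue_index(r)
        out[consensus.ids[r]] = {
            idx[c] for c in kept_columns if idx[c] is not None
        }
    return out


# ---------------------------------------------------------------------------
# Synthetic bundle generator (testing / benchmarking aid)


def random_alignment_bundle(
    rng: np.random.Generator,
    n_seqs: int = 4,
    seq_len: int = 12,
    ncol: int = 18,
    n_alternatives: int = 3,
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY",
) -> tuple[Alignment, list[Alignment]]:
    """Generate a synthetic consensus plus alternative alignments.

    The same ungapped sequences are given independent random gap placements
    in every alignment — deliberately noisy input for exercising the
    column-support machinery, not a model of real aligner output.
    """
    if ncol < seq_len:
        raise ValueError("ncol must be >= seq_len")
    ids = [f"s{i}" for i in range(n_seqs)]
    seqs = [
        "".join(rng.choice(list(alphabet), size=seq_len)) for _ in range(n_seqs)
    ]

    def random_gapping() -> Alignment:
        rows = []
        for seq in seqs:
            cols = sorted(rng.choice(ncol, size=len(seq), replace=False))
            row = [GAP] * ncol
            for pos, c in enumerate(cols):
                row[c] = seq[pos]
            rows.append("".join(row))
        return Alignment(list(ids), rows)

    consensus = random_gapping()
    alternatives = [random_gapping() for _ in range(n_alternatives)]
    return consensus, alternatives
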