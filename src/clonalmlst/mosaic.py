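"""Intragenic mosaic display and MaxChi breakpoint scanning.

``polymorphic_matrix`` renders the classic polymorphic-site table: only
variable alignment columns are shown, with dots marking identity to a
chosen reference row, so mosaic blocks shared with different putative
parents are visible by eye.

``maxchi_breakpoints`` is a maximum chi-square recombination detector for a
(parent A, parent B, child) triplet: at informative sites — columns where
the parents differ and the child matches exactly one of them — a true
crossover produces a run of A-matches on one side of the breakpoint and
B-matches on the other. Every cut point between informative sites is scored
with the 2×2 chi-square of (matches A / matches B) × (left / right); the
maximizing cut is the candidate breakpoint and its significance comes from
permuting the site labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignio import LocusAlignment


@dataclass
class PolymorphicSiteMatrix:
    locus_name: str
    site_positions: list[int]  # 1-based alignment columns
    reference_row: str
    rows: list[tuple[str, str]]  # (label, dot-masked bases)

    def render(self) -> str:
        """Plain-text table: position header (vertical digits) + rows."""
        width = max((len(str(p)) for p in self.site_positions), default=1)
        label_w = max((len(lbl) for lbl, _ in self.rows), default=0)
        lines = []
        for digit in range(width):
            header = "".join(
                str(p).rjust(width)[digit] for p in self.site_positions
            )
            lines.append(" " * label_w + " " + header)
        for label, bases in self.rows:
            lines.append(label.ljust(label_w) + " " + bases)
        return "\n".join(lines)


def polymorphic_matrix(
    aln: LocusAlignment, reference: str | None = None
) -> PolymorphicSiteMatrix:
    """Extract variable columns; dot-mask identity to the reference row."""
    if aln.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    if reference is None:
        reference = aln.isolate_ids[0]
    if reference not in aln.isolate_ids:
        raise KeyError(f"reference {reference!r} not in alignment")
    mat = np.array([list(s) for s in aln.sequences], dtype="U1")
    variable = [
        col
        for col in range(aln.length)
        if len(set(mat[:, col].tolist()) - {"-", "N"}) >= 2
    ]
    ref_seq = aln.sequence_of(reference)
    rows = []
    for label, seq in zip(aln.isolate_ids, aln.sequences):
        if label == reference:
            rows.append((label, "".join(seq[c] for c in variable)))
        else:
            rows.append(
                (
                    label,
                    "".join(
                        "." if seq[c] == ref_seq[c] else seq[c] for c in variable
                    ),
                )
            )
    return PolymorphicSiteMatrix(
        locus_name=aln.locus_name,
        site_positions=[c + 1 for c in variable],
        reference_row=reference,
        rows=rows,
    )


@dataclass
class BreakpointCall:
    """One MaxChi scan result for a parent/parent/child triplet."""

    position: float  # candidate breakpoint (1-based alignment coordinate)
    statistic: float
    permutation_p: float
    n_informative: int
    informative_positions: list[int]
    cut_index: int  # informative sites 0..cut_index-1 lie left of the cut
    no_call: bool = False
    reason: str | None = None


def _max_chi_over_cuts(
    matches_a: np.ndarray, min_side: int
) -> tuple[float, int]:
    """Max 2x2 chi-square over cuts; ties go to the leftmost cut.

    ``matches_a`` is the boolean informative-site vector (True = child
    matches parent A). Returns (statistic, cut index k), where sites
    [0, k) are left of the cut.
    """
    m = matches_a.size
    x = matches_a.astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(x)])
    total_a = int(cum[-1])
    total_b = m - total_a
    ks = np.arange(min_side, m - min_side + 1)
    a_left = cum[ks].astype(float)  # child==A, left
    b_left = ks - a_left
    a_right = total_a - a_left
    b_right = total_b - b_left
    row1 = a_left + b_left
    row2 = a_right + b_right
    col1 = a_left + a_right
    col2 = b_left + b_right
    denom = row1 * row2 * col1 * col2
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(
            denom > 0,
            m * (a_left * b_right - b_left * a_right) ** 2 / denom,
            0.0,
        )
    best = int(np.argmax(chi2))  # argmax takes the first (leftmost) maximum
    return float(chi2[best]), int(ks[best])


def maxchi_breakpoints(
    parent_a: str,
    parent_b: str,
    child: str,
    min_sites_per_side: int = 3,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> BreakpointCall:
    """MaxChi scan of a triplet of equal-length aligned sequences.

    Informative sites are columns where both parents carry determinate,
    differing bases and the child matches exactly one parent. The reported
    ``position`` is the midpoint between the flanking informative sites of
    the best cut. The permutation p-value shuffles which sites match which
    parent, keeping the totals fixed.
    """
    if not (len(parent_a) == len(parent_b) == len(child)):
        raise ValueError("sequences must have equal length")
    if min_sites_per_side < 2:
        raise ValueError("min_sites_per_side must be >= 2")
    length = len(child)
    positions: list[int] = []
    matches: list[bool] = []
    for col, (a, b, c) in enumerate(zip(parent_a, parent_b, child)):
        if "-" in (a, b, c) or "N" in (a, b, c):
            continue
        if a == b:
            continue
        if c == a:
            positions.append(col + 1)
            matches.append(True)
        elif c == b:
            positions.append(col + 1)
            matches.append(False)
    m = len(positions)
    if m < 2 * min_sites_per_side:
        return BreakpointCall(
            position=float("nan"),
            statistic=float("nan"),
            permutation_p=float("nan"),
            n_informative=m,
            informative_positions=positions,
            cut_index=-1,
            no_call=True,
            reason=f"only {m} informative sites "
            f"(need {2 * min_sites_per_side})",
        )
    x = np.array(matches, dtype=bool)
    stat, cut = _max_chi_over_cuts(x, min_sites_per_side)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm_stat, _ = _max_chi_over_cuts(rng.permutation(x), min_sites_per_side)
        if perm_stat >= stat:
            exceed += 1
    p = (exceed + 1) / (n_permutations + 1)
    position = (positions[cut - 1] + positions[cut]) / 2.0
    assert 0 < position < length + 1
    return BreakpointCall(
        position=position,
        statistic=stat,
        permutation_p=p,
        n_informative=m,
        informative_positions=positions,
        cut_index=cut,
    )


def write_breakpoints_tsv(calls: list[BreakpointCall], labels: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "triplet\tposition\tstatistic\tpermutation_p\tn_informative\tno_call\n"
        )
        for label, c in zip(labels, calls):
            fh.write(
                f"{label}\t{c.position:.1f}\t{c.statistic:.4f}\t"
                f"{c.permutation_p:.5f}\t{c.n_informative}\t{int(c.no_call)}\n"
            )
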