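"""Master regulator analysis: regulon enrichment against a signature.

Each TF's regulon (its network targets) is tested for overlap with the
prognostic signature by a one-sided Fisher exact test; p-values are adjusted
by Benjamini-Hochberg, and significant TFs are ranked by signature coverage
using competition ranking (ties share the minimum rank of their group).
"""

from __future__ import annotations

import logging

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ConsensusNetwork, MRARow, PrognetError, Regulon, Signature

logger = logging.getLogger(__name__)


def extract_regulons(net: ConsensusNetwork) -> list[Regulon]:
    """One regulon per regulator with at least one (non-self) target."""
    targets: dict[str, set[str]] = {}
    for e in net.edges:
        targets.setdefault(e.regulator, set()).add(e.target)
    out = []
    for tf in sorted(targets):
        tgts = targets[tf] - {tf}
        if tgts:
            out.append(Regulon(tf, tgts))
    return out


def fisher_enrichment_p(overlap: int, regulon_size: int, sig_size: int, universe: int) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 overlap table.

    Equals the hypergeometric upper tail P(X >= overlap) with ``sig_size``
    marked genes, ``regulon_size`` draws, from a universe of ``universe``.
    """
    if universe < 1:
        raise PrognetError("empty universe")
    if overlap > min(regulon_size, sig_size):
        raise PrognetError("overlap exceeds regulon or signature size")
    return float(stats.hypergeom.sf(overlap - 1, universe, sig_size, regulon_size))


def bh_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise PrognetError(f"p-value outside [0, 1]: {p}")
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def mra_enrichment(
    regulons: list[Regulon], sig: Signature, universe: set[str]
) -> list[MRARow]:
    """Fisher enrichment of every regulon against the signature.

    ``universe`` is the gene background for the 2x2 table — by default the
    caller passes all genes in the network.  Signature genes outside the
    universe are dropped with a warning.
    """
    if not universe:
        raise PrognetError("empty universe")
    sig_genes = set(sig.genes)
    outside = sig_genes - universe
    if outside:
        logger.warning("dropping %d signature gene(s) outside universe", len(outside))
        sig_genes = sig_genes & universe
    rows: list[MRARow] = []
    for reg in regulons:
        tgts = reg.targets & universe
        overlap = len(tgts & sig_genes)
        p = fisher_enrichment_p(overlap, len(tgts), len(sig_genes), len(universe))
        rows.append(MRARow(tf=reg.tf, regulon_size=len(reg.targets),
                           overlap=overlap, p_value=p))
    fdrs = bh_fdr([r.p_value for r in rows])
    for row, fdr in zip(rows, fdrs):
        row.fdr = fdr
    return rows


def competition_ranks(coverages: list[int]) -> list[int]:
    """Competition ("1224") ranks for coverages sorted descending on entry."""
    order = sorted(range(len(coverages)), key=lambda i: -coverages[i])
    ranks = [0] * len(coverages)
    for pos, i in enumerate(order):
        if pos > 0 and coverages[i] == coverages[order[pos - 1]]:
            ranks[i] = ranks[order[pos - 1]]
        else:
            ranks[i] = pos + 1
    return ranks


def rank_and_select(rows: list[MRARow], fdr_cut: float = 0.05, k: int = 10) -> list[MRARow]:
    """Rank significant TFs by signature coverage; select the top ``k``.

    Only rows with FDR < ``fdr_cut`` compete.  Ranks are competition ranks
    on coverage (descending).  ``selected`` marks rows whose rank <= k; a
    tie group beginning at rank <= k is selected whole, so k acts as a floor
    when the boundary falls inside a tie.  Reporting order within a tie
    group is ascending FDR, then descending regulon size, then TF id.
    """
    if k < 1:
        raise PrognetError("k must be >= 1")
    sig_rows = [r for r in rows if r.fdr < fdr_cut]
    other = [r for r in rows if r.fdr >= fdr_cut]
    ranks = competition_ranks([r.overlap for r in sig_rows])
    for r, rank in zip(sig_rows, ranks):
        r.rank = rank
        r.selected = rank <= k
    for r in other:
        r.rank = 0
        r.selected = False
    ordered = sorted(
        sig_rows, key=lambda r: (r.rank, r.fdr, -r.regulon_size, r.tf)
    ) + sorted(other, key=lambda r: (-r.overlap, r.fdr, r.tf))
    return ordered


def selected_tfs(rows: list[MRARow]) -> list[str]:
    return [r.tf for r in rows if r.selected]


def union_coverage(rows: list[MRARow], regulons: list[Regulon], sig: Signature) -> int:
    """Distinct signature genes covered by the selected TFs."""
    chosen = set(selected_tfs(rows))
    sig_genes = set(sig.genes)
    covered: set[str] = set()
    for reg in regulons:
        if reg.tf in chosen:
            covered |= reg.targets & sig_genes
    return len(covered)


def selection_overlap(a: list[MRARow], b: list[MRARow]) -> tuple[set[str], set[str]]:
    """(intersection, union) of two selected-TF sets."""
    sa, sb = set(selected_tfs(a)), set(selected_tfs(b))
    return sa & sb, sa | sb
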