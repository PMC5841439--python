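"""Term enrichment with an odds-ratio-threshold null.

For each term a 2x2 table of (in foreground) x (annotated to term) over the
background is tested one-sided. The null hypothesis is not independence but
"log odds ratio < 1" (natural log, i.e. odds ratio below e); the p-value is
the upper tail of Fisher's noncentral hypergeometric distribution with
noncentrality equal to the threshold odds ratio. Setting the threshold to 1
recovers the central one-sided Fisher exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import nchypergeom_fisher


@dataclass
class TermAnnotation:
    term_id: str
    term_name: str
    genes: set[str] = field(default_factory=set)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    fg_in: int
    fg_size: int
    bg_in: int
    bg_size: int
    log_odds_ratio: float
    p: float


def read_terms_tsv(path: str) -> list[TermAnnotation]:
    """Read a flat term-annotation table (term_id, term_name, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms: dict[str, TermAnnotation] = {}
    for row in df.itertuples(index=False):
        t = terms.setdefault(row.term_id, TermAnnotation(row.term_id, row.term_name))
        t.genes.add(row.gene)
    return list(terms.values())


def noncentral_upper_p(
    fg_in: int, fg_size: int, bg_in: int, bg_size: int, odds_ratio: float
) -> float:
    """P(X >= fg_in) for X ~ Fisher noncentral hypergeometric with population
    bg_size, bg_in annotated, fg_size drawn, noncentrality odds_ratio."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio threshold must be positive")
    lo = max(0, fg_size - (bg_size - bg_in))
    hi = min(bg_in, fg_size)
    if fg_in <= lo:
        return 1.0
    # sum the pmf over the upper support: the distribution's sf() loses
    # precision in deep tails, the pmf does not
    ks = np.arange(fg_in, hi + 1)
    p = float(
        np.sum(nchypergeom_fisher.pmf(ks, bg_size, bg_in, fg_size, odds_ratio))
    )
    return min(max(p, 0.0), 1.0)


def _sample_log_or(a: int, b: int, c: int, d: int) -> float:
    """Log sample odds ratio; Haldane-Anscombe 0.5 correction when a margin
    cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return math.log((a * d) / (b * c))


def enrich(
    foreground: set[str],
    background: set[str],
    terms: list[TermAnnotation],
    or_null_threshold: float = math.e,
    p_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Test each term for enrichment of the foreground within the background.

    Terms with no gene in the background are skipped. Results are sorted by
    p-value; ``significant`` corresponds to p < ``p_threshold`` and is left
    to the caller/table writer.
    """
    if not foreground <= background:
        raise ValueError("foreground must be a subset of the background")
    results = []
    fg_size = len(foreground)
    bg_size = len(background)
    for term in terms:
        annotated = term.genes & background
        if not annotated:
            continue
        fg_in = len(term.genes & foreground)
        bg_in = len(annotated)
        a = fg_in
        b = fg_size - fg_in
        c = bg_in - fg_in
        d = (bg_size - fg_size) - c
        p = noncentral_upper_p(fg_in, fg_size, bg_in, bg_size, or_null_threshold)
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                fg_in=fg_in,
                fg_size=fg_size,
                bg_in=bg_in,
                bg_size=bg_size,
                log_odds_ratio=_sample_log_or(a, b, c, d),
                p=p,
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_table(
    results: list[EnrichmentResult], p_threshold: float = 0.05
) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "fg_in": r.fg_in,
                "fg_size": r.fg_size,
                "bg_in": r.bg_in,
                "bg_size": r.bg_size,
                "log_odds_ratio": r.log_odds_ratio,
                "p": r.p,
            }
            for r in results
        ]
    )
    if not df.empty:
        df["significant"] = df["p"] < p_threshold
        # optional BH column for readers who want FDR control across terms
        from .dasmodel import bh_adjust

        df["q_bh"] = bh_adjust(df["p"].to_numpy())
    return df
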