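"""Splicing-signature connectivity mapping for splicing-factor discovery.

A splicing signature assigns each event a symbol from {+, -, 0}. For a
splicing-factor (SF) perturbation dataset, + means the event is positively
regulated by the SF: inclusion rises under overexpression (OE) or falls
under knockdown/knockout (KD/KO). For a disease dataset the signature is
oriented by the SF's own expression direction: with the SF up in disease, an
event with increased inclusion is +; with the SF down, decreased inclusion
is +. A 3x3 contingency table over the common events is collapsed into 2x2
tables testing enrichment of ++ and -- agreement by one-sided Fisher exact
tests; an SF is a candidate regulator when the tests are significant
(default: both must pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

SYMBOLS = ("+", "-", "0")


@dataclass
class PerturbationMeta:
    dataset_id: str
    sf_gene: str
    direction: str  # OE | KD | KO

    def __post_init__(self):
        if self.direction not in ("OE", "KD", "KO"):
            raise ValueError(f"unknown perturbation direction {self.direction!r}")


@dataclass
class ComparisonResult:
    sf_gene: str
    dataset_id: str
    table: pd.DataFrame  # 3x3, rows perturbation symbol x cols disease symbol
    p_pp: float
    p_mm: float
    candidate: bool


def read_perturbation_meta(path: str) -> list[PerturbationMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        PerturbationMeta(r.dataset_id, r.sf_gene, r.direction)
        for r in df.itertuples(index=False)
    ]


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors (DESeq contract).

    ``matrix`` is genes x samples. Only genes with non-zero counts in every
    sample contribute; each sample's factor is the median of its counts over
    their per-gene geometric means.
    """
    counts = matrix.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError(
            "no gene has non-zero counts in all samples; filter the matrix"
        )
    sub = counts[nonzero]
    log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_geo)
    return pd.Series(np.median(ratios, axis=0), index=matrix.columns)


def sf_direction(
    matrix: pd.DataFrame,
    sf_gene: str,
    case_samples: list[str],
    control_samples: list[str],
) -> str:
    """'up'/'down'/'undetermined' from the normalized fold change of the SF's
    own gene between case and control samples."""
    if sf_gene not in matrix.index:
        raise KeyError(f"gene {sf_gene} not in expression matrix")
    factors = size_factors(matrix)
    norm = matrix.loc[sf_gene] / factors
    mean_case = norm[case_samples].mean()
    mean_ctrl = norm[control_samples].mean()
    if mean_ctrl == 0 or mean_case == mean_ctrl:
        return "undetermined"
    return "up" if mean_case > mean_ctrl else "down"


def _das_symbols(das: pd.DataFrame, dpsi: float, q: float) -> pd.Series:
    """Raw per-event change symbols: + for inclusion up, - for down, 0 else."""
    up = (das["delta_psi"] > dpsi) & (das["q"] < q)
    down = (das["delta_psi"] < -dpsi) & (das["q"] < q)
    sym = pd.Series("0", index=das["event_id"].to_numpy(), dtype=object)
    sym[up.to_numpy()] = "+"
    sym[down.to_numpy()] = "-"
    return sym


def perturbation_signature(
    das: pd.DataFrame,
    meta: PerturbationMeta,
    dpsi_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.Series:
    """Signature of an SF perturbation dataset (event_id -> symbol).

    Under OE, inclusion up => +; under KD/KO the mapping flips.
    """
    sym = _das_symbols(das, dpsi_threshold, q_threshold)
    if meta.direction in ("KD", "KO"):
        sym = sym.map({"+": "-", "-": "+", "0": "0"})
    return sym


def disease_signature(
    das: pd.DataFrame,
    sf_dir: str,
    dpsi_threshold: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.Series:
    """Disease signature oriented by the SF's expression direction.

    Raises ValueError for 'undetermined' (the SF is skipped upstream).
    """
    if sf_dir not in ("up", "down"):
        raise ValueError(
            f"cannot orient disease signature for SF direction {sf_dir!r}"
        )
    sym = _das_symbols(das, dpsi_threshold, q_threshold)
    if sf_dir == "down":
        sym = sym.map({"+": "-", "-": "+", "0": "0"})
    return sym


def _collapse(table: pd.DataFrame, symbol: str) -> list[list[int]]:
    n_ss = int(table.loc[symbol, symbol])
    n_s_other = int(table.loc[symbol].sum() - n_ss)
    n_other_s = int(table[symbol].sum() - n_ss)
    n_other_other = int(table.to_numpy().sum() - n_ss - n_s_other - n_other_s)
    return [[n_ss, n_s_other], [n_other_s, n_other_other]]


def compare_signatures(
    sig_perturb: pd.Series,
    sig_disease: pd.Series,
    sf_gene: str = "",
    dataset_id: str = "",
    alpha: float = 0.05,
    rule: str = "both",
) -> ComparisonResult:
    """Tabulate the 3x3 table over common events and test ++/-- enrichment.

    ``rule`` = 'both' requires both one-sided Fisher tests significant for a
    candidate call; 'any' requires either.
    """
    common = sig_perturb.index.intersection(sig_disease.index)
    if len(common) == 0:
        raise ValueError("no common events between signatures")
    table = pd.DataFrame(0, index=list(SYMBOLS), columns=list(SYMBOLS))
    pairs = pd.crosstab(sig_perturb.loc[common], sig_disease.loc[common])
    for r in pairs.index:
        for c in pairs.columns:
            table.loc[r, c] = pairs.loc[r, c]
    _, p_pp = fisher_exact(_collapse(table, "+"), alternative="greater")
    _, p_mm = fisher_exact(_collapse(table, "-"), alternative="greater")
    if rule == "both":
        candidate = (p_pp < alpha) and (p_mm < alpha)
    elif rule == "any":
        candidate = (p_pp < alpha) or (p_mm < alpha)
    else:
        raise ValueError(f"unknown candidate rule {rule!r}")
    return ComparisonResult(
        sf_gene=sf_gene,
        dataset_id=dataset_id,
        table=table,
        p_pp=float(p_pp),
        p_mm=float(p_mm),
        candidate=candidate,
    )


def conserved_event_regulators(
    conserved_event_ids: list[str],
    perturb_signatures: dict[str, pd.Series],
    disease_signatures: dict[str, pd.Series],
) -> dict[str, list[str]]:
    """Attribute conserved events to SFs: an SF is listed for an event iff
    the event's symbol is non-zero in the SF's perturbation signature and
    identical in the matching disease signature (++ or --)."""
    out: dict[str, list[str]] = {}
    for sf, psig in perturb_signatures.items():
        dsig = disease_signatures.get(sf)
        if dsig is None:
            continue
        hits = []
        for ev in conserved_event_ids:
            sp = psig.get(ev, "0")
            sd = dsig.get(ev, "0")
            if sp != "0" and sp == sd:
                hits.append(ev)
        if hits:
            out[sf] = hits
    return out
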