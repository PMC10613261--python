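"""Posterior summaries: PIPs, FDR-controlled SNP calls, credible sets.

The posterior inclusion probability of SNP j aggregates the K component
posteriors, PIP_j = 1 - prod_k (1 - pi_kj).  SNP selection controls the
global FDR by the running mean of sorted local false discovery rates
(fdr_j = 1 - PIP_j).  Each component yields a level-alpha credible set (the
smallest SNP set whose component posterior mass reaches alpha); sets whose
purity (minimum absolute pairwise LD) falls below a threshold in every
population are flagged as redundant and discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import LDMatrix

DEFAULT_COVERAGE = 0.95
DEFAULT_PURITY = 0.1
DEFAULT_FDR = 0.1


@dataclass
class CredibleSet:
    """Level-alpha credible set of one causal-signal component."""

    component: int
    snps: np.ndarray          # ordered by descending component posterior
    indices: np.ndarray
    coverage: float
    purity: np.ndarray = field(default_factory=lambda: np.array([]))  # per pop
    kept: bool = True
    duplicate_of: int | None = None

    @property
    def size(self) -> int:
        return len(self.indices)


@dataclass
class SelectionResult:
    """Global-FDR selection at level xi."""

    pip: np.ndarray
    local_fdr: np.ndarray
    selected: np.ndarray      # indices, in selection (ascending local-fdr) order
    xi: float

    @property
    def n_selected(self) -> int:
        return len(self.selected)


def compute_pip(pi_tilde: np.ndarray, active: np.ndarray | None = None) -> np.ndarray:
    """PIP_j = 1 - prod_k (1 - pi_kj) over active components."""
    pi = np.asarray(pi_tilde, dtype=float)
    if active is not None:
        pi = pi[np.asarray(active, dtype=bool)]
    if pi.shape[0] == 0:
        return np.zeros(pi.shape[1] if pi.ndim == 2 else 0)
    return 1.0 - np.prod(1.0 - pi, axis=0)


def global_fdr_select(pip: np.ndarray, xi: float) -> SelectionResult:
    """Select SNPs whose running-mean local fdr stays below xi.

    SNPs are sorted by local fdr (1 - PIP) ascending, ties broken by the
    original SNP order; the j-th ordered SNP is selected if the mean of the
    first j local fdrs is strictly below xi.  Because the running mean of an
    ascending sequence is non-decreasing, the selection is a prefix.
    """
    pip = np.asarray(pip, dtype=float)
    local_fdr = 1.0 - pip
    order = np.argsort(local_fdr, kind="stable")
    cummean = np.cumsum(local_fdr[order]) / np.arange(1, len(pip) + 1)
    below = cummean < xi
    n_sel = int(np.max(np.nonzero(below)[0]) + 1) if below.any() else 0
    return SelectionResult(pip=pip, local_fdr=local_fdr,
                           selected=order[:n_sel], xi=xi)


def credible_set(pi_k: np.ndarray, alpha: float = DEFAULT_COVERAGE,
                 component: int = 0,
                 snp_id: np.ndarray | None = None) -> CredibleSet:
    """Smallest SNP set reaching cumulative component mass alpha.

    SNPs are added in descending posterior order (ties broken by original
    SNP order) until the cumulative sum reaches alpha.
    """
    pi_k = np.asarray(pi_k, dtype=float)
    order = np.argsort(-pi_k, kind="stable")
    csum = np.cumsum(pi_k[order])
    size = int(np.searchsorted(csum, alpha) + 1)
    size = min(size, len(pi_k))
    idx = order[:size]
    if snp_id is None:
        snp_id = np.arange(len(pi_k))
    return CredibleSet(component=component,
                       snps=np.asarray(snp_id, dtype=object)[idx],
                       indices=idx, coverage=float(csum[size - 1]))


def purity_filter(cs: CredibleSet, lds: list[LDMatrix],
                  threshold: float = DEFAULT_PURITY) -> CredibleSet:
    """Attach per-population purity and the kept flag.

    Purity is the minimum absolute pairwise correlation among the set's
    SNPs in one population (singletons have purity 1 by convention).  A set
    is discarded only when its purity is below the threshold in *every*
    population: redundant components spread mass over uncorrelated SNPs in
    all ancestries at once.
    """
    idx = cs.indices
    purities = []
    for ld in lds:
        if np.any(idx >= ld.p):
            raise ValueError("credible-set SNP missing from LD matrix")
        if len(idx) == 1:
            purities.append(1.0)
            continue
        sub = np.abs(ld.R[np.ix_(idx, idx)])
        off = sub[np.triu_indices(len(idx), k=1)]
        purities.append(float(off.min()))
    cs.purity = np.asarray(purities)
    cs.kept = bool(np.any(cs.purity >= threshold))
    return cs


def extract_credible_sets(fit, lds: list[LDMatrix],
                          alpha: float = DEFAULT_COVERAGE,
                          purity: float = DEFAULT_PURITY) -> list[CredibleSet]:
    """Credible sets of all active components, purity-filtered and with
    duplicate sets (identical SNP membership) flagged."""
    sets: list[CredibleSet] = []
    for k in range(fit.state.K):
        if not fit.active[k]:
            continue
        cs = credible_set(fit.state.pi[k], alpha=alpha, component=k,
                          snp_id=fit.snp_id)
        cs = purity_filter(cs, lds, threshold=purity)
        sets.append(cs)
    seen: dict[tuple, int] = {}
    for cs in sets:
        key = tuple(sorted(cs.indices.tolist()))
        if key in seen:
            cs.duplicate_of = seen[key]
        else:
            seen[key] = cs.component
    return sets


def credible_sets_frame(sets: list[CredibleSet], pi: np.ndarray) -> pd.DataFrame:
    """Long-format table: one row per (component, SNP)."""
    rows = []
    for cs in sets:
        for rank, (snp, j) in enumerate(zip(cs.snps, cs.indices)):
            rows.append({
                "component": cs.component,
                "rank": rank,
                "snp": snp,
                "pi": pi[cs.component, j],
                "coverage": cs.coverage,
                **{f"purity_pop{t + 1}": v for t, v in enumerate(cs.purity)},
                "kept": cs.kept,
                "duplicate_of": -1 if cs.duplicate_of is None else cs.duplicate_of,
            })
    return pd.DataFrame(rows)
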