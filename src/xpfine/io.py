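"""Reading, validation and cross-population harmonization of GWAS inputs.

Summary statistics are whitespace/tab-delimited text with a header
(default column names ``SNP A1 A2 BETA SE N Z``, remappable).  LD matrices
are dense whitespace text or ``.npy`` containers with a one-SNP-per-line
sidecar file.  ``harmonize`` intersects the SNP sets of all populations,
resolves swapped effect/other alleles by flipping signs, drops
strand-ambiguous (A/T, C/G) SNPs, and subsets every LD matrix to one
common SNP order (the order of population 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

log = logging.getLogger(__name__)

#: default column names of a summary-statistics file
DEFAULT_COLUMNS: dict[str, str] = {
    "snp": "SNP",
    "a1": "A1",
    "a2": "A2",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
    "z": "Z",
}

#: allele pairs whose strand cannot be resolved without frequencies
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

_Z_CONSISTENCY_TOL = 1e-6


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SummaryStats:
    """Marginal GWAS summary statistics for one population.

    ``bhat`` and ``se`` are on the standardized-genotype scale; ``n`` is the
    per-SNP GWAS sample size.  ``z`` is optional and must equal
    ``bhat / se`` when present.
    """

    snp_id: np.ndarray
    allele_effect: np.ndarray
    allele_other: np.ndarray
    bhat: np.ndarray
    se: np.ndarray
    n: np.ndarray
    z: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele_effect = np.char.upper(np.asarray(self.allele_effect, dtype=str))
        self.allele_other = np.char.upper(np.asarray(self.allele_other, dtype=str))
        self.bhat = np.asarray(self.bhat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n = np.broadcast_to(np.asarray(self.n, dtype=float), self.bhat.shape).copy()
        if self.z is not None:
            self.z = np.asarray(self.z, dtype=float)
        self.validate()

    @property
    def p(self) -> int:
        return self.snp_id.shape[0]

    def validate(self) -> None:
        lengths = {arr.shape[0] for arr in (self.snp_id, self.allele_effect,
                                            self.allele_other, self.bhat,
                                            self.se, self.n)}
        if self.z is not None:
            lengths.add(self.z.shape[0])
        if len(lengths) != 1:
            raise InputError("summary-statistic columns have unequal lengths")
        if not np.all(np.isfinite(self.bhat)):
            raise InputError("non-finite effect estimates")
        if not (np.all(np.isfinite(self.se)) and np.all(self.se > 0)):
            raise InputError("standard errors must be finite and > 0")
        if len(set(self.snp_id.tolist())) != self.p:
            raise InputError("duplicate SNP ids")
        if self.z is not None and self.p > 0:
            if np.max(np.abs(self.z - self.bhat / self.se)) >= _Z_CONSISTENCY_TOL:
                raise InputError("z column inconsistent with bhat/se")

    @property
    def zscores(self) -> np.ndarray:
        """z-scores, computed from bhat/se if no z column was supplied."""
        if self.z is not None:
            return self.z
        return self.bhat / self.se

    def subset(self, idx: np.ndarray) -> "SummaryStats":
        return SummaryStats(
            snp_id=self.snp_id[idx],
            allele_effect=self.allele_effect[idx],
            allele_other=self.allele_other[idx],
            bhat=self.bhat[idx],
            se=self.se[idx],
            n=self.n[idx],
            z=None if self.z is None else self.z[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "SNP": self.snp_id,
            "A1": self.allele_effect,
            "A2": self.allele_other,
            "BETA": self.bhat,
            "SE": self.se,
            "N": self.n,
            "Z": self.zscores,
        })


@dataclass
class LDMatrix:
    """SNP correlation matrix of one population, with its SNP id sidecar."""

    snp_id: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise InputError("LD matrix must be square")
        if self.R.shape[0] != self.snp_id.shape[0]:
            raise InputError("LD matrix size does not match SNP list length")
        if np.max(np.abs(self.R - self.R.T)) > 1e-8:
            raise InputError("LD matrix not symmetric within 1e-8")
        if np.max(np.abs(np.diag(self.R) - 1.0)) > 1e-6:
            raise InputError("LD matrix diagonal not 1 within 1e-6")

    @property
    def p(self) -> int:
        return self.R.shape[0]

    def subset(self, idx: np.ndarray) -> "LDMatrix":
        return LDMatrix(self.snp_id[idx], self.R[np.ix_(idx, idx)])


@dataclass
class AlignedDataset:
    """Per-population summary statistics and LD restricted to one shared,
    allele-consistent SNP set in a single common order (population 1's)."""

    stats: list[SummaryStats]
    lds: list[LDMatrix]
    audit: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["snp", "population", "action", "detail"]))

    def __post_init__(self) -> None:
        if len(self.stats) < 1 or len(self.stats) != len(self.lds):
            raise InputError("need matching stats/LD per population")
        ref = self.stats[0].snp_id
        for st, ld in zip(self.stats, self.lds):
            if not np.array_equal(st.snp_id, ref) or not np.array_equal(ld.snp_id, ref):
                raise InputError("populations do not share one SNP order")

    @property
    def T(self) -> int:
        return len(self.stats)

    @property
    def p(self) -> int:
        return self.stats[0].p

    @property
    def snp_id(self) -> np.ndarray:
        return self.stats[0].snp_id

    def write_audit(self, path: str | Path) -> None:
        """Write the drop/flip audit log as tab-delimited text."""
        self.audit.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_sumstats(path: str | Path,
                  column_map: Mapping[str, str] | None = None) -> SummaryStats:
    """Read one population's summary statistics from delimited text.

    Rows with missing or non-finite effect/SE (or SE <= 0) are dropped and
    counted.  A z-only table (no BETA/SE columns) is accepted when N is
    present: effects are reconstructed as ``bhat = z/sqrt(n)``,
    ``se = 1/sqrt(n)``.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=r"\s+", dtype={cols["snp"]: str})
    for key in ("snp", "a1", "a2"):
        if cols[key] not in df.columns:
            raise ConfigurationError(f"required column '{cols[key]}' missing in {path}")

    has_beta = cols["beta"] in df.columns and cols["se"] in df.columns
    has_z = cols["z"] in df.columns
    has_n = cols["n"] in df.columns
    if not has_beta and not (has_z and has_n):
        raise ConfigurationError(
            f"{path}: need BETA/SE columns, or Z with N for reconstruction")
    if not has_n:
        raise ConfigurationError(f"required column '{cols['n']}' missing in {path}")

    n_raw = len(df)
    if has_beta:
        bhat = pd.to_numeric(df[cols["beta"]], errors="coerce")
        se = pd.to_numeric(df[cols["se"]], errors="coerce")
    else:
        nvec = pd.to_numeric(df[cols["n"]], errors="coerce")
        zvec = pd.to_numeric(df[cols["z"]], errors="coerce")
        bhat = zvec / np.sqrt(nvec)
        se = 1.0 / np.sqrt(nvec)
    keep = np.isfinite(bhat) & np.isfinite(se) & (se > 0)
    n_dropped = int(n_raw - keep.sum())
    if n_dropped:
        log.info("%s: dropped %d rows with missing/invalid effect or SE",
                 path.name, n_dropped)
    df = df.loc[keep.values].reset_index(drop=True)
    bhat = bhat[keep].to_numpy()
    se = se[keep].to_numpy()

    dup = df[cols["snp"]].duplicated(keep=False)
    if dup.any():
        # multi-allelic / repeated ids cannot be aligned unambiguously
        log.warning("%s: dropped %d rows with duplicated SNP ids",
                    path.name, int(dup.sum()))
        keep2 = ~dup.to_numpy()
        df = df.loc[keep2].reset_index(drop=True)
        bhat, se = bhat[keep2], se[keep2]
    if len(df) == 0:
        raise InputError(f"{path}: no usable rows after validation")

    z = None
    if has_z and has_beta:
        z = pd.to_numeric(df[cols["z"]], errors="coerce").to_numpy()
        if not np.all(np.isfinite(z)):
            z = None
    return SummaryStats(
        snp_id=df[cols["snp"]].to_numpy(dtype=object),
        allele_effect=df[cols["a1"]].to_numpy(dtype=str),
        allele_other=df[cols["a2"]].to_numpy(dtype=str),
        bhat=bhat,
        se=se,
        n=pd.to_numeric(df[cols["n"]], errors="coerce").to_numpy(),
        z=z,
    )


def psd_repair(R: np.ndarray) -> np.ndarray:
    """Project a near-correlation matrix onto the PSD cone.

    Negative eigenvalues are clipped at zero, the matrix reconstructed and
    rescaled back to unit diagonal.  Reference-panel LD estimated on finite
    samples (or subsetted after shrinkage) is near-PSD, so the perturbation
    is small; downstream variational updates need the repaired form.
    """
    R = 0.5 * (R + R.T)
    w, V = np.linalg.eigh(R)
    if w[0] >= 0:
        out = R.copy()
    else:
        out = (V * np.clip(w, 0.0, None)) @ V.T
        d = np.sqrt(np.clip(np.diag(out), 1e-12, None))
        out = out / np.outer(d, d)
        out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 1.0)
    return out


def load_ld(path: str | Path, snp_path: str | Path) -> LDMatrix:
    """Load an LD matrix (dense text or ``.npy``) plus its SNP sidecar.

    The matrix is symmetrized as ``(R + R.T)/2``, PSD-repaired and its
    diagonal reset to exactly 1.
    """
    path, snp_path = Path(path), Path(snp_path)
    if not path.exists():
        raise InputError(f"LD matrix file not found: {path}")
    if not snp_path.exists():
        raise InputError(f"LD SNP sidecar not found: {snp_path}")
    if path.suffix == ".npy":
        R = np.load(path)
    else:
        R = np.loadtxt(path, ndmin=2)
    snps = [line.strip() for line in snp_path.read_text().splitlines() if line.strip()]
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise InputError(f"{path}: LD matrix is not square (shape {R.shape})")
    if R.shape[0] != len(snps):
        raise InputError(
            f"{path}: matrix size {R.shape[0]} != {len(snps)} SNPs in sidecar")
    if np.max(np.abs(R)) > 1.0 + 1e-3:
        raise InputError(f"{path}: correlation entries exceed 1 beyond tolerance")
    R = 0.5 * (R + R.T)
    np.clip(R, -1.0, 1.0, out=R)
    R = psd_repair(R)
    return LDMatrix(np.asarray(snps, dtype=object), R)


def compute_ld_from_genotypes(G: np.ndarray,
                              snp_id: Sequence[str] | None = None) -> LDMatrix:
    """Sample LD ``R = G'G/n`` from an n x p standardized genotype matrix."""
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise InputError("genotype matrix must be n x p with n >= 2")
    n, p = G.shape
    R = G.T @ G / n
    np.clip(R, -1.0, 1.0, out=R)
    R = psd_repair(R)
    if snp_id is None:
        snp_id = [f"snp{j}" for j in range(p)]
    return LDMatrix(np.asarray(snp_id, dtype=object), R)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------


def _allele_relation(a1: str, o1: str, a2: str, o2: str) -> str:
    if (a1, o1) == (a2, o2):
        return "same"
    if (a1, o1) == (o2, a2):
        return "swap"
    return "mismatch"


def harmonize(stats: Sequence[SummaryStats],
              lds: Sequence[LDMatrix],
              drop_ambiguous: bool = True) -> AlignedDataset:
    """Align >=2 populations to the shared, allele-consistent SNP set.

    Population 1's SNP order is canonical.  Where the effect/other alleles
    of a later population are swapped relative to population 1, the signs of
    its ``bhat`` (and ``z``) are flipped; irreconcilable allele pairs are
    dropped with a warning.  Strand-ambiguous (A/T, C/G) SNPs are dropped by
    default because allele frequencies are not an input and strand cannot be
    resolved.  All actions are recorded in the audit table.
    """
    if len(stats) < 2:
        raise InputError("harmonize requires at least two populations")
    if len(stats) != len(lds):
        raise InputError("one LD matrix per population required")

    audit_rows: list[dict] = []

    # restrict each LD matrix (a superset is allowed) to its population's SNPs
    per_pop_ld: list[LDMatrix] = []
    for t, (st, ld) in enumerate(zip(stats, lds)):
        pos = {s: i for i, s in enumerate(ld.snp_id)}
        missing = [s for s in st.snp_id if s not in pos]
        if missing:
            raise InputError(
                f"population {t + 1}: {len(missing)} SNPs absent from its LD matrix "
                f"(e.g. {missing[0]})")
        idx = np.fromiter((pos[s] for s in st.snp_id), dtype=int, count=st.p)
        per_pop_ld.append(ld.subset(idx))

    shared = set(stats[0].snp_id.tolist())
    for st in stats[1:]:
        shared &= set(st.snp_id.tolist())
    if not shared:
        raise InputError("empty SNP intersection across populations")

    ref = stats[0]
    ref_index = {s: i for i, s in enumerate(ref.snp_id)}
    order = [s for s in ref.snp_id if s in shared]

    keep: list[str] = []
    flips: dict[int, set[str]] = {t: set() for t in range(1, len(stats))}
    for s in order:
        i0 = ref_index[s]
        a1, o1 = ref.allele_effect[i0], ref.allele_other[i0]
        if drop_ambiguous and (a1, o1) in AMBIGUOUS_PAIRS:
            audit_rows.append({"snp": s, "population": 0,
                               "action": "drop", "detail": "strand-ambiguous"})
            continue
        ok = True
        for t, st in enumerate(stats[1:], start=1):
            it = int(np.nonzero(st.snp_id == s)[0][0])
            rel = _allele_relation(a1, o1, st.allele_effect[it], st.allele_other[it])
            if rel == "mismatch":
                log.warning("SNP %s: irreconcilable alleles (%s/%s vs %s/%s), dropped",
                            s, a1, o1, st.allele_effect[it], st.allele_other[it])
                audit_rows.append({"snp": s, "population": t,
                                   "action": "drop", "detail": "allele-mismatch"})
                ok = False
                break
            if rel == "swap":
                flips[t].add(s)
        if ok:
            keep.append(s)
    if not keep:
        raise InputError("no SNPs left after allele harmonization")

    out_stats: list[SummaryStats] = []
    out_lds: list[LDMatrix] = []
    for t, (st, ld) in enumerate(zip(stats, per_pop_ld)):
        pos = {s: i for i, s in enumerate(st.snp_id)}
        idx = np.fromiter((pos[s] for s in keep), dtype=int, count=len(keep))
        sub = st.subset(idx)
        if t > 0 and flips[t]:
            flip_mask = np.fromiter((s in flips[t] for s in keep), dtype=bool)
            bhat = sub.bhat.copy()
            bhat[flip_mask] *= -1.0
            z = None if sub.z is None else np.where(flip_mask, -sub.z, sub.z)
            a_eff = sub.allele_effect.copy()
            a_oth = sub.allele_other.copy()
            a_eff[flip_mask], a_oth[flip_mask] = (sub.allele_other[flip_mask],
                                                  sub.allele_effect[flip_mask])
            sub = SummaryStats(sub.snp_id, a_eff, a_oth, bhat, sub.se, sub.n, z)
            for s in sorted(flips[t]):
                audit_rows.append({"snp": s, "population": t,
                                   "action": "flip", "detail": "swapped alleles"})
        out_stats.append(sub)
        ld_pos = {s: i for i, s in enumerate(ld.snp_id)}
        ld_idx = np.fromiter((ld_pos[s] for s in keep), dtype=int, count=len(keep))
        out_lds.append(ld.subset(ld_idx))

    audit = pd.DataFrame(audit_rows, columns=["snp", "population", "action", "detail"])
    log.info("harmonized %d populations to %d shared SNPs (%d dropped, %d flipped)",
             len(stats), len(keep),
             int((audit["action"] == "drop").sum()) if len(audit) else 0,
             int((audit["action"] == "flip").sum()) if len(audit) else 0)
    return AlignedDataset(stats=out_stats, lds=out_lds, audit=audit)
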