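"""Allele-frequency introgression statistics with block-jackknife errors.

ABBA/BABA D, f3, outgroup-f3, f4 and the f4-ratio admixture proportion,
computed from per-site population allele frequencies.  Standard errors come
from a weighted block jackknife over contiguous genomic blocks (default
5 Mb), which is robust to linkage between nearby sites; significance uses
the conventional |Z| > 3 cut-off (two-sided normal p < 0.0027; the one-sided
convention p < 0.00135 is what |Z| > 3 corresponds to for a signed
expectation) and the normal-approximation p-value is reported alongside.

Estimators are the frequency generalizations of the count forms: with
frequencies in {0, 1} they reduce exactly to pattern counting.  No
small-sample bias-correction terms are applied; the plain products of
frequency differences are used as printed in the formulas above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrequencyTable",
    "read_frequency_table",
    "JackknifeResult",
    "block_jackknife_ratio",
    "d_statistic",
    "f3",
    "outgroup_f3",
    "f4",
    "f4_ratio",
]

DEFAULT_BLOCK_SIZE = 5_000_000


@dataclass
class FrequencyTable:
    """Per-site derived/alternate allele frequencies for several populations.

    ``data`` holds columns CHROM, POS (1-based) plus one float column per
    population; positions must be strictly increasing within a chromosome
    and frequencies must lie in [0, 1].
    """

    data: pd.DataFrame
    populations: tuple[str, ...]
    polarization: str = "unpolarized"

    def __post_init__(self):
        self.data = self.data.reset_index(drop=True)
        cols = list(self.data.columns)
        if cols[:2] != ["CHROM", "POS"]:
            raise ValueError("first columns must be CHROM, POS")
        missing = [p for p in self.populations if p not in cols]
        if missing:
            raise ValueError(f"missing population columns: {missing}")
        for chrom, grp in self.data.groupby("CHROM", sort=False):
            pos = grp["POS"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")
        vals = self.data[list(self.populations)].to_numpy()
        if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
            raise ValueError("frequencies must be in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.data)

    def freq(self, pop: str) -> np.ndarray:
        if pop not in self.populations:
            raise KeyError(f"unknown population {pop!r}")
        return self.data[pop].to_numpy(dtype=float)

    def block_ids(self, block_size: int = DEFAULT_BLOCK_SIZE) -> np.ndarray:
        """Contiguous non-overlapping genomic blocks, numbered globally.

        Blocks are ``block_size``-bp tiles per chromosome; the last partial
        tile of each chromosome is kept as its own block.
        """
        if block_size <= 0:
            raise ValueError("block_size must be > 0")
        ids = np.empty(len(self.data), dtype=np.int64)
        offset = 0
        for _, grp in self.data.groupby("CHROM", sort=False):
            local = (grp["POS"].to_numpy() - 1) // block_size
            # renumber to consecutive ids so empty tiles don't count
            uniq, inv = np.unique(local, return_inverse=True)
            ids[grp.index.to_numpy()] = inv + offset
            offset += len(uniq)
        return ids

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def read_frequency_table(path, polarization: str = "unpolarized") -> FrequencyTable:
    """Read a TSV with columns CHROM, POS and one column per population."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    pops = tuple(c for c in df.columns if c not in ("CHROM", "POS"))
    df = df.reset_index(drop=True)
    return FrequencyTable(df, pops, polarization)


# ---------------------------------------------------------------------------
# jackknife machinery


@dataclass
class JackknifeResult:
    """A statistic with its weighted block-jackknife standard error."""

    statistic: str
    populations: tuple[str, ...]
    estimate: float
    se: float
    z: float
    p_value: float
    n_blocks: int
    block_size: int
    n_sites: int
    extra: Optional[dict] = None

    @property
    def significant(self) -> bool:
        """The |Z| > 3 convention (normal p < 0.00135 one-sided)."""
        return abs(self.z) > 3

    def summary(self) -> str:
        pops = ", ".join(self.populations)
        s = (
            f"{self.statistic}({pops}) = {self.estimate:.6g}  "
            f"SE = {self.se:.3g}  Z = {self.z:.3f}  p = {self.p_value:.3g}  "
            f"[{self.n_blocks} blocks of {self.block_size} bp, {self.n_sites} sites]"
        )
        if self.extra:
            s += "  " + "  ".join(f"{k}={v:.4g}" for k, v in self.extra.items())
        return s


def block_jackknife_ratio(
    num: np.ndarray,
    den: np.ndarray,
    blocks: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> tuple[float, float, int, int]:
    """Weighted block jackknife of a ratio statistic Σ num / Σ den.

    ``weights`` are per-site block weights (default 1 per site with data);
    per-block weights are their block sums.  Returns (estimate, se,
    n_blocks, n_sites).  For a statistic linear in sites (den constant 1)
    the jackknife point estimate coincides with the plain estimate.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if weights is None:
        weights = np.ones_like(num)
    ok = np.isfinite(num) & np.isfinite(den)
    num, den, blocks, weights = num[ok], den[ok], blocks[ok], weights[ok]
    if den.sum() == 0:
        raise ValueError("no informative sites (zero denominator)")
    uniq, inv = np.unique(blocks, return_inverse=True)
    G = len(uniq)
    N = np.bincount(inv, weights=num, minlength=G)
    D = np.bincount(inv, weights=den, minlength=G)
    m = np.bincount(inv, weights=weights, minlength=G)
    keep = m > 0
    N, D, m = N[keep], D[keep], m[keep]
    G = len(N)
    n = m.sum()
    theta = N.sum() / D.sum()
    if G < 2:
        return float(theta), float("nan"), G, int(ok.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        theta_minus = (N.sum() - N) / (D.sum() - D)
    theta_minus = np.where(np.isfinite(theta_minus), theta_minus, theta)
    h = n / m
    theta_jack = G * theta - np.sum((1.0 - m / n) * theta_minus)
    pseudo = h * theta - (h - 1.0) * theta_minus
    var = np.sum((pseudo - theta_jack) ** 2 / (h - 1.0)) / G
    return float(theta), float(np.sqrt(var)), G, int(ok.sum())


def _result(
    name: str,
    pops: Sequence[str],
    num: np.ndarray,
    den: np.ndarray,
    ft: FrequencyTable,
    block_size: int,
    informative: Optional[np.ndarray] = None,
    extra: Optional[dict] = None,
) -> JackknifeResult:
    blocks = ft.block_ids(block_size)
    weights = informative.astype(float) if informative is not None else None
    est, se, n_blocks, n_sites = block_jackknife_ratio(num, den, blocks, weights)
    z = est / se if se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
    return JackknifeResult(
        name, tuple(pops), est, se, float(z), float(p), n_blocks, block_size,
        n_sites, extra,
    )


# ---------------------------------------------------------------------------
# statistics


def d_statistic(
    ft: FrequencyTable,
    A: str,
    B: str,
    C: str,
    D: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> JackknifeResult:
    """ABBA/BABA D for the rooted tree (((A, B), C), D).

    D = Σ(ABBA - BABA) / Σ(ABBA + BABA) with the frequency generalization
    ABBAᵢ = (1-aᵢ)bᵢcᵢ(1-dᵢ), BABAᵢ = aᵢ(1-bᵢ)cᵢ(1-dᵢ).  Without gene flow
    between A/B and C the expectation is 0; a positive D means B shares an
    excess of derived alleles with C.
    """
    if len({A, B, C, D}) != 4:
        raise ValueError("populations must be distinct")
    a, b, c, d = (ft.freq(p) for p in (A, B, C, D))
    abba = (1 - a) * b * c * (1 - d)
    baba = a * (1 - b) * c * (1 - d)
    den = abba + baba
    if np.nansum(den) == 0:
        raise ValueError("no informative sites")
    return _result(
        "D", (A, B, C, D), abba - baba, den, ft, block_size,
        informative=(den > 0),
    )


def f3(
    ft: FrequencyTable,
    test: str,
    ref1: str,
    ref2: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> JackknifeResult:
    """f3(Test; Ref1, Ref2) = (1/N) Σ (tᵢ - r1ᵢ)(tᵢ - r2ᵢ).

    A significantly negative value (Z < -3) is unambiguous evidence that the
    test population is admixed between relatives of the two references.
    """
    if len({test, ref1, ref2}) != 3:
        raise ValueError("populations must be distinct")
    if ft.n_sites == 0:
        raise ValueError("empty frequency table")
    t, r1, r2 = ft.freq(test), ft.freq(ref1), ft.freq(ref2)
    num = (t - r1) * (t - r2)
    return _result("f3", (test, ref1, ref2), num, np.ones_like(num), ft, block_size)


def outgroup_f3(
    ft: FrequencyTable,
    outgroup: str,
    a: str,
    x: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> JackknifeResult:
    """Outgroup-f3 F3(O; A, X): shared drift of A and X since the outgroup.

    Higher values across candidate X populations mean more shared alleles
    with A; used as a ranking statistic.
    """
    res = f3(ft, outgroup, a, x, block_size)
    return JackknifeResult(
        "outgroup_f3", (outgroup, a, x), res.estimate, res.se, res.z,
        res.p_value, res.n_blocks, res.block_size, res.n_sites,
    )


def rank_outgroup_f3(
    ft: FrequencyTable,
    outgroup: str,
    a: str,
    candidates: Iterable[str],
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> list[JackknifeResult]:
    """Outgroup-f3 of every candidate X against A, sorted high to low."""
    out = [outgroup_f3(ft, outgroup, a, x, block_size) for x in candidates]
    return sorted(out, key=lambda r: -r.estimate)


def f4(
    ft: FrequencyTable,
    p1: str,
    p2: str,
    p3: str,
    p4: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> JackknifeResult:
    """f4(P1, P2; P3, P4) = (1/N) Σ (p1ᵢ - p2ᵢ)(p3ᵢ - p4ᵢ)."""
    if len({p1, p2, p3, p4}) != 4:
        raise ValueError("populations must be distinct")
    a, b, c, d = (ft.freq(p) for p in (p1, p2, p3, p4))
    num = (a - b) * (c - d)
    return _result("f4", (p1, p2, p3, p4), num, np.ones_like(num), ft, block_size)


def f4_ratio(
    ft: FrequencyTable,
    A: str,
    O: str,
    X: str,
    B: str,
    C: str,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> JackknifeResult:
    """Admixture proportion α = f4(A, O; X, C) / f4(A, O; B, C).

    Assumes the phylogeny (((A, B), C), O) with X a mixture of B-related
    (proportion α) and C-related (1 - α) ancestry.  The jackknife deletes
    one block at a time and recomputes the full ratio.
    """
    if len({A, O, X, B, C}) != 5:
        raise ValueError("populations must be distinct")
    a, o, x, b, c = (ft.freq(p) for p in (A, O, X, B, C))
    num = (a - o) * (x - c)
    den = (a - o) * (b - c)
    if np.nansum(np.abs(den)) == 0:
        raise ValueError("zero denominator f4")
    den_res = f4(ft, A, O, B, C, block_size)
    if abs(den_res.z) < 1:
        import warnings

        warnings.warn("uninformative denominator f4 (|Z| < 1); ratio unreliable")
    res = _result(
        "f4_ratio", (A, O, X, B, C), num, den, ft, block_size,
        extra={"denominator_f4": den_res.estimate, "denominator_z": den_res.z},
    )
    return res
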