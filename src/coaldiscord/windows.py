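"""Window-based genome scans: Dxy, species-specific mutations, binomial null.

Sites arrive as a table (CHROM, POS, one allele column per species); windows
are non-overlapping tiles (default 500 kb) in 0-based half-open coordinates
(1-based input positions are converted).  A site is *informative* for a
comparison when every involved species has an unambiguous A/C/G/T allele.

The binomial null models the per-window count of focal-species-specific
mutations in the absence of introgression: an expected count is drawn from a
normal prior (truncated at zero), a window is picked uniformly, and a
binomial count is drawn with that window's informative sites as trials.  A
genome harboring introgressed segments from a diverged (ghost) donor shows
an excess of high-count windows that this null cannot reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WindowTable",
    "filter_windows",
    "sliding_dxy",
    "species_specific_counts",
    "binomial_null",
    "BinomialNullResult",
    "site_table_from_alignment",
    "read_site_table",
]

DEFAULT_WINDOW = 500_000
_VALID = frozenset("ACGT")


def read_site_table(path) -> pd.DataFrame:
    """TSV with CHROM, POS (1-based) and one allele column per species."""
    df = pd.read_csv(path, sep="\t", dtype={"CHROM": str})
    if list(df.columns[:2]) != ["CHROM", "POS"]:
        raise ValueError("first columns must be CHROM, POS")
    return df


def site_table_from_alignment(
    sequences: dict[str, str], chrom: str = "1", start: int = 1
) -> pd.DataFrame:
    """Columnize an aligned set of equal-length sequences into a site table.

    ``start`` is the 1-based position of the first alignment column.
    """
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    (L,) = lengths
    data = {"CHROM": [chrom] * L, "POS": np.arange(start, start + L)}
    for name, seq in sequences.items():
        data[name] = list(seq.upper())
    return pd.DataFrame(data)


def _check_sorted(df: pd.DataFrame) -> None:
    for chrom, grp in df.groupby("CHROM", sort=False):
        if np.any(np.diff(grp["POS"].to_numpy()) <= 0):
            raise ValueError(f"site table not sorted by position on {chrom}")


def _window_frame(
    df: pd.DataFrame, window: int, cols: Sequence[str]
) -> pd.DataFrame:
    """Aggregate boolean site columns into tiled windows per chromosome."""
    pos0 = df["POS"].to_numpy() - 1  # to 0-based
    widx = pos0 // window
    out = (
        df.assign(_w=widx)
        .groupby(["CHROM", "_w"], sort=True)[list(cols)]
        .sum()
        .reset_index()
    )
    out["start"] = out["_w"] * window
    out["end"] = out["start"] + window
    out = out.rename(columns={"CHROM": "chrom"}).drop(columns="_w")
    return out[["chrom", "start", "end", *cols]]


@dataclass
class WindowTable:
    """Tiled per-window counts; ``data`` columns: chrom, start, end,
    informative_sites, count, scaled_count (+ statistic-specific extras)."""

    data: pd.DataFrame
    window: int
    n_total: int
    n_removed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.data)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"#{k}={v}\n")
            self.data.to_csv(fh, sep="\t", index=False)


def filter_windows(df: pd.DataFrame, min_informative: int) -> tuple[pd.DataFrame, int]:
    """Drop windows with fewer than ``min_informative`` informative sites.

    Returns the retained frame and the number removed (retained + removed
    equals the input row count).
    """
    kept = df[df["informative_sites"] >= min_informative].reset_index(drop=True)
    return kept, len(df) - len(kept)


def sliding_dxy(
    site_table: pd.DataFrame,
    a: str,
    b: str,
    window: int = DEFAULT_WINDOW,
) -> WindowTable:
    """Pairwise divergence per window: differing bases / informative sites.

    Windows with no informative sites get ``dxy`` = NaN.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    _check_sorted(site_table)
    aa = site_table[a].astype(str).str.upper()
    bb = site_table[b].astype(str).str.upper()
    informative = aa.isin(_VALID) & bb.isin(_VALID)
    diff = informative & (aa != bb)
    df = site_table[["CHROM", "POS"]].assign(
        informative_sites=informative.astype(int), count=diff.astype(int)
    )
    wt = _window_frame(df, window, ["informative_sites", "count"])
    with np.errstate(invalid="ignore", divide="ignore"):
        wt["dxy"] = wt["count"] / wt["informative_sites"]
    wt["scaled_count"] = wt["dxy"] * window
    return WindowTable(wt, window, n_total=len(wt), meta={"statistic": "dxy", "pair": f"{a},{b}"})


def species_specific_counts(
    site_table: pd.DataFrame,
    focal: str,
    window: int = DEFAULT_WINDOW,
    min_informative: int = 250_000,
    species: Optional[Sequence[str]] = None,
) -> WindowTable:
    """Count focal-species-specific mutations per window.

    A site is focal-specific iff every non-focal species carries one shared
    unambiguous allele and the focal allele differs from it.  Windows with
    fewer than ``min_informative`` informative sites are dropped (their
    number is recorded; retained + removed = total).
    """
    _check_sorted(site_table)
    if species is None:
        species = [c for c in site_table.columns if c not in ("CHROM", "POS")]
    if focal not in species:
        raise ValueError(f"focal species {focal!r} not in table")
    others = [s for s in species if s != focal]
    alleles = {s: site_table[s].astype(str).str.upper() for s in species}
    informative = np.ones(len(site_table), dtype=bool)
    for s in species:
        informative &= alleles[s].isin(_VALID).to_numpy()
    shared = np.ones(len(site_table), dtype=bool)
    first = alleles[others[0]]
    for s in others[1:]:
        shared &= (alleles[s] == first).to_numpy()
    specific = informative & shared & (alleles[focal] != first).to_numpy()
    df = site_table[["CHROM", "POS"]].assign(
        informative_sites=informative.astype(int), count=specific.astype(int)
    )
    wt = _window_frame(df, window, ["informative_sites", "count"])
    n_total = len(wt)
    kept, _ = filter_windows(wt, min_informative)
    with np.errstate(invalid="ignore", divide="ignore"):
        kept["scaled_count"] = kept["count"] * window / kept["informative_sites"]
    return WindowTable(
        kept,
        window,
        n_total=n_total,
        n_removed=n_total - len(kept),
        meta={
            "statistic": "species_specific",
            "focal": focal,
            "min_informative": min_informative,
        },
    )


@dataclass
class BinomialNullResult:
    """Simulated null distribution of per-window counts vs the observed one."""

    simulated: np.ndarray
    observed: np.ndarray
    ks_statistic: float
    ks_p_value: float
    consistent: bool
    quantiles: pd.DataFrame
    meta: dict

    def summary(self) -> str:
        verdict = "consistent with" if self.consistent else "NOT consistent with"
        return (
            f"Binomial null: {len(self.simulated)} simulations, "
            f"{len(self.observed)} observed windows\n"
            f"  simulated mean {self.simulated.mean():.1f} (SD {self.simulated.std():.1f}); "
            f"observed mean {self.observed.mean():.1f} (SD {self.observed.std():.1f})\n"
            f"  KS = {self.ks_statistic:.4f}, p = {self.ks_p_value:.3g} "
            f"-> observed distribution {verdict} the no-introgression null"
        )


def binomial_null(
    windows: WindowTable,
    prior_mean: float = 494.0,
    prior_sd: float = 117.0,
    n_sims: int = 100_000,
    target_length: int = DEFAULT_WINDOW,
    seed: int = 0,
    alpha: float = 0.01,
    mu_per: str = "simulation",
) -> BinomialNullResult:
    """Simulate the no-introgression null for per-window specific counts.

    Per simulation an expected count μ is drawn from Normal(prior_mean,
    prior_sd) truncated at 0, a window is picked uniformly, and a count is
    drawn from Binomial(nᵢ, μ/nᵢ) with nᵢ that window's informative sites;
    draws are scaled to ``target_length``.  The observed ``scaled_count``
    distribution is compared with the simulated one by a two-sample
    Kolmogorov-Smirnov test; ``consistent`` is KS p > ``alpha``.

    ``mu_per`` may be "simulation" (one μ per draw, default) -- with a single
    window per draw the two interpretations coincide, the knob is kept for
    symmetry with multi-window batch simulation.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if prior_sd <= 0:
        raise ValueError("prior_sd must be > 0")
    if mu_per not in ("simulation", "window"):
        raise ValueError("mu_per must be 'simulation' or 'window'")
    info = windows.data["informative_sites"].to_numpy(dtype=float)
    span = (windows.data["end"] - windows.data["start"]).to_numpy(dtype=float)
    if len(info) == 0:
        raise ValueError("empty window table")
    rng = np.random.default_rng([seed, 0xB10])
    a = (0.0 - prior_mean) / prior_sd
    mu = stats.truncnorm.rvs(
        a, np.inf, loc=prior_mean, scale=prior_sd, size=n_sims, random_state=rng
    )
    idx = rng.integers(0, len(info), size=n_sims)
    n = info[idx]
    p = mu / n
    clamped = p > 1.0
    if clamped.mean() > 0.5:
        raise ValueError("prior inconsistent with window sizes (p = μ/n > 1)")
    p = np.clip(p, 0.0, 1.0)
    draws = rng.binomial(n.astype(np.int64), p)
    simulated = draws * (target_length / span[idx])
    observed = windows.data["scaled_count"].to_numpy(dtype=float)
    observed = observed[np.isfinite(observed)]
    ks = stats.ks_2samp(observed, simulated)
    qs = [0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99]
    quant = pd.DataFrame(
        {
            "quantile": qs,
            "observed": np.quantile(observed, qs),
            "simulated": np.quantile(simulated, qs),
        }
    )
    return BinomialNullResult(
        simulated,
        observed,
        float(ks.statistic),
        float(ks.pvalue),
        bool(ks.pvalue > alpha),
        quant,
        meta={
            "prior_mean": prior_mean,
            "prior_sd": prior_sd,
            "n_sims": n_sims,
            "target_length": target_length,
            "seed": seed,
            "mu_per": mu_per,
            "model": "normal prior on expected count, binomial draw per window",
        },
    )
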