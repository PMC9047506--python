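"""delta(SNP index) scan with a depth-conditional simulated null band.

At every retained site delta = index_BY - index_KY. Candidate sites are
those whose delta falls outside a two-sided confidence band built from
1,000 replicates of the no-QTL null. Each null replicate draws, for each
bulk independently, an allele count k ~ Binomial(2 n_bulk, 1/2) — the
chromosomes sampled into a bulk from an unselected F2 — turns it into a
true frequency k/(2 n_bulk), then draws the observed reads
Binomial(depth, frequency) at the site's actual depth. The band is the
empirical (lower, upper) quantile pair of the replicate deltas, computed
per distinct (depth_BY, depth_KY) pair so low-coverage sites get
appropriately wide bands. Candidate sites are merged into regions by
gap distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variant_filtering import SnpIndexRecord

logger = logging.getLogger(__name__)


@dataclass
class ScanResult:
    """Per-site delta(SNP index), its null band, and the candidate flag."""

    record: SnpIndexRecord
    delta: float
    ci_low: float
    ci_high: float
    is_candidate: bool
    smoothed: float | None = None

    @property
    def chrom(self) -> str:
        return self.record.site.chrom

    @property
    def pos(self) -> int:
        return self.record.site.pos


@dataclass
class CandidateRegion:
    """A run of candidate sites on one chromosome, spanned inclusively."""

    chrom: str
    start: int
    end: int
    sites: list[ScanResult] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def delta_snp_index(record: SnpIndexRecord) -> float:
    """delta = index_BY - index_KY (fixed orientation, sterile bulk first)."""
    if record.index_by is None or record.index_ky is None:
        raise ValueError(
            f"{record.site.chrom}:{record.site.pos}: delta undefined without coverage"
        )
    return record.index_by - record.index_ky


def _null_deltas(
    n_bulk: int,
    depth_by: int,
    depth_ky: int,
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    chroms = 2 * n_bulk
    f_by = rng.binomial(chroms, 0.5, size=n_reps) / chroms
    f_ky = rng.binomial(chroms, 0.5, size=n_reps) / chroms
    idx_by = rng.binomial(depth_by, f_by) / depth_by
    idx_ky = rng.binomial(depth_ky, f_ky) / depth_ky
    return idx_by - idx_ky


def simulate_null_band(
    n_bulk: int,
    depth_by: int,
    depth_ky: int,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided null band for delta at one (depth_BY, depth_KY) pair.

    Returns the empirical inverse-CDF quantiles at (1-level)/2 and
    1-(1-level)/2 over ``n_reps`` two-stage binomial replicates; with the
    default level the 2.5th and 97.5th percentiles. Quantiles use the
    'inverted_cdf' rule so they always land on the discrete null support
    and the band is conservative by construction.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie strictly between 0 and 1")
    if n_bulk <= 0 or depth_by <= 0 or depth_ky <= 0:
        raise ValueError("bulk size and depths must be strictly positive")
    if n_reps < 100:
        warnings.warn(
            f"n_reps={n_reps} gives a noisy band; use >= 100", stacklevel=2
        )
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(depth_by, depth_ky))
        )
    deltas = _null_deltas(n_bulk, depth_by, depth_ky, n_reps, rng)
    tail = (1 - level) / 2
    lo, hi = np.quantile(deltas, [tail, 1 - tail], method="inverted_cdf")
    return float(lo), float(hi)


class NullBandSimulator:
    """Caches null bands per (depth_BY, depth_KY) so equal-depth sites share one.

    Each depth pair gets its own deterministic RNG stream split from
    ``seed``, so the band at a given pair is identical regardless of the
    order sites are scanned in.
    """

    def __init__(
        self, n_bulk: int, n_reps: int = 1000, level: float = 0.95, seed: int = 0
    ) -> None:
        if not 0 < level < 1:
            raise ValueError("level must lie strictly between 0 and 1")
        self.n_bulk = n_bulk
        self.n_reps = n_reps
        self.level = level
        self.seed = seed
        self._cache: dict[tuple[int, int], tuple[float, float]] = {}

    def band(self, depth_by: int, depth_ky: int) -> tuple[float, float]:
        key = (depth_by, depth_ky)
        if key not in self._cache:
            self._cache[key] = simulate_null_band(
                self.n_bulk,
                depth_by,
                depth_ky,
                n_reps=self.n_reps,
                level=self.level,
                seed=self.seed,
            )
        return self._cache[key]


def site_permutation_band(
    record: SnpIndexRecord,
    n_reps: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Alternative null: reassign the site's pooled reads between the bulks.

    The reads of both bulks are pooled and randomly redealt preserving each
    bulk's depth; the band is the same quantile pair over the permuted
    deltas. This conditions on the observed allele counts instead of the
    F2 sampling model.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    d_by, d_ky = record.depth_by, record.depth_ky
    if d_by == 0 or d_ky == 0:
        raise ValueError("permutation band undefined at zero depth")
    site = record.site
    allele = "alt"  # orientation cancels in the two-sided band
    high_by = site.ad["BY"][1] if allele == "alt" else site.ad["BY"][0]
    high_ky = site.ad["KY"][1]
    total_high = high_by + high_ky
    total = d_by + d_ky
    # hypergeometric redeal of the pooled high-allele reads into the BY slot
    by_high = rng.hypergeometric(total_high, total - total_high, d_by, size=n_reps)
    deltas = by_high / d_by - (total_high - by_high) / d_ky
    tail = (1 - level) / 2
    lo, hi = np.quantile(deltas, [tail, 1 - tail], method="inverted_cdf")
    return float(lo), float(hi)


def scan_records(
    records: list[SnpIndexRecord],
    n_bulk: int,
    n_reps: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    band_simulator: NullBandSimulator | None = None,
    null: str = "simulated",
) -> list[ScanResult]:
    """Compute delta and the null band at every site; flag candidates.

    A site is a candidate iff its delta lies strictly outside the band.
    """
    if null not in ("simulated", "site-permutation"):
        raise ValueError("null must be 'simulated' or 'site-permutation'")
    if band_simulator is None and null == "simulated":
        band_simulator = NullBandSimulator(n_bulk, n_reps, level, seed)
    perm_rng = np.random.default_rng(seed)
    results = []
    for rec in records:
        delta = delta_snp_index(rec)
        if null == "simulated":
            lo, hi = band_simulator.band(rec.depth_by, rec.depth_ky)
        else:
            lo, hi = site_permutation_band(rec, n_reps, level, perm_rng)
        results.append(
            ScanResult(rec, delta, lo, hi, bool(delta < lo or delta > hi))
        )
    return results


def call_candidates_and_merge(
    results: list[ScanResult],
    merge_gap: int = 1_000_000,
    min_sites: int = 3,
) -> list[CandidateRegion]:
    """Merge candidate sites within ``merge_gap`` bp into regions.

    Regions carrying fewer than ``min_sites`` member sites are dropped.
    Input is sorted internally by (chrom, pos) when needed.
    """
    ordered = sorted(results, key=lambda r: (r.chrom, r.pos))
    if [(r.chrom, r.pos) for r in results] != [(r.chrom, r.pos) for r in ordered]:
        logger.info("scan results were unsorted; sorted internally")
    regions: list[CandidateRegion] = []
    current: list[ScanResult] = []
    for res in ordered:
        if not res.is_candidate:
            continue
        if current and (
            res.chrom != current[-1].chrom or res.pos - current[-1].pos > merge_gap
        ):
            regions.append(_close_region(current))
            current = []
        current.append(res)
    if current:
        regions.append(_close_region(current))
    return [r for r in regions if r.n_sites >= min_sites]


def _close_region(sites: list[ScanResult]) -> CandidateRegion:
    return CandidateRegion(
        chrom=sites[0].chrom,
        start=min(s.pos for s in sites),
        end=max(s.pos for s in sites),
        sites=list(sites),
    )


def sliding_window_delta(
    results: list[ScanResult], window: int = 1_000_000, step: int = 10_000
) -> pd.DataFrame:
    """Window-mean delta per chromosome (plotting aid; calling is site-wise)."""
    rows = []
    frame = scan_to_frame(results)
    for chrom, sub in frame.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy()
        delta = sub["delta"].to_numpy()
        if len(pos) == 0:
            continue
        centers = np.arange(pos.min(), pos.max() + 1, step)
        half = window // 2
        for c in centers:
            mask = (pos >= c - half) & (pos <= c + half)
            if mask.any():
                rows.append({"chrom": chrom, "pos": int(c), "delta": delta[mask].mean()})
    return pd.DataFrame(rows)


def scan_to_frame(results: list[ScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in results],
            "pos": [r.pos for r in results],
            "delta": [r.delta for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "is_candidate": [r.is_candidate for r in results],
        }
    )


def write_scan_outputs(
    results: list[ScanResult],
    regions: list[CandidateRegion],
    scan_path: str,
    regions_path: str,
) -> None:
    """Write the per-site scan TSV and the regions BED (0-based half-open)."""
    scan_to_frame(results).to_csv(scan_path, sep="\t", index=False)
    with open(regions_path, "w") as fh:
        for i, reg in enumerate(regions, 1):
            fh.write(
                f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\tregion{i}\t{reg.n_sites}\n"
            )


def plot_scan(
    results: list[ScanResult],
    regions: list[CandidateRegion],
    path: str,
    window: int = 1_000_000,
    step: int = 10_000,
) -> None:
    """Per-chromosome delta(SNP index) panel with the null band and regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = scan_to_frame(results)
    smooth = sliding_window_delta(results, window, step)
    chroms = sorted(frame["chrom"].unique())
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(9, 2.4 * len(chroms)), squeeze=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = frame[frame["chrom"] == chrom]
        ax.scatter(sub["pos"] / 1e6, sub["delta"], s=4, c="0.6", label="delta")
        ax.plot(sub["pos"] / 1e6, sub["ci_low"], lw=0.7, c="tab:blue")
        ax.plot(sub["pos"] / 1e6, sub["ci_high"], lw=0.7, c="tab:blue", label="95% CI")
        ssub = smooth[smooth["chrom"] == chrom]
        if not ssub.empty:
            ax.plot(ssub["pos"] / 1e6, ssub["delta"], lw=1.2, c="tab:red", label="window mean")
        for reg in regions:
            if reg.chrom == chrom:
                ax.axvspan(reg.start / 1e6, reg.end / 1e6, color="tab:orange", alpha=0.2)
        ax.set_ylim(-1.05, 1.05)
        ax.set_ylabel("delta(SNP index)")
        ax.set_title(chrom)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
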