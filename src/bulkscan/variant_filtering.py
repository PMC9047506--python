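"""Allelic-depth parsing, per-bulk SNP index, and site quality filters.

The SNP index of a bulk at one site is the fraction of its reads carrying a
designated *high parent*'s allele. That allele is resolved from the parents'
own read counts, not from ref/alt identity, because the reference line is
neither parent of the cross; this fixes the sign convention of the
downstream delta(SNP index).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import pandas as pd
import pysam

from .synthetic_data import PARENTS, SAMPLES

logger = logging.getLogger(__name__)

BULKS = ("BY", "KY")


class VariantFormatError(ValueError):
    """A VCF record or header lacks a required sample or the AD field."""


@dataclass(frozen=True)
class SnpSite:
    """One biallelic SNP with (ref, alt) read counts for the four samples."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    ad: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
            raise ValueError(f"{self.chrom}:{self.pos}: not a SNP")
        missing = set(SAMPLES) - set(self.ad)
        if missing:
            raise ValueError(f"{self.chrom}:{self.pos}: missing samples {missing}")
        for sample, (r, a) in self.ad.items():
            if r < 0 or a < 0:
                raise ValueError(f"{self.chrom}:{self.pos}: negative depth for {sample}")

    def depth(self, sample: str) -> int:
        r, a = self.ad[sample]
        return r + a

    def alt_fraction(self, sample: str) -> float | None:
        r, a = self.ad[sample]
        return a / (r + a) if r + a else None


@dataclass
class SnpIndexRecord:
    """Per-bulk SNP index at one site, plus filter state.

    ``index_by``/``index_ky`` are ``None`` (and ``flag`` set) when the bulk
    has no coverage — an index is undefined at depth 0, never coerced to 0.
    """

    site: SnpSite
    high_parent: str
    index_by: float | None
    index_ky: float | None
    depth_by: int
    depth_ky: int
    flag: str | None = None
    passed: bool | None = None
    reason: str | None = None


class ParsedVariants(NamedTuple):
    sites: list[SnpSite]
    n_skipped_multiallelic: int
    n_skipped_non_snp: int


def read_allelic_depths(path: str) -> ParsedVariants:
    """Read biallelic SNPs with per-sample AD from a VCF.

    Samples are resolved by header name (column order is irrelevant);
    multiallelic and non-SNP records are skipped and counted.
    """
    with pysam.VariantFile(path) as vcf:
        present = set(vcf.header.samples)
        missing = set(SAMPLES) - present
        if missing:
            raise VariantFormatError(
                f"{path}: VCF lacks required samples {sorted(missing)}"
            )
        sites: list[SnpSite] = []
        n_multi = n_non_snp = 0
        for rec in vcf:
            alts = rec.alts or ()
            if len(alts) != 1:
                n_multi += 1
                continue
            if len(rec.ref) != 1 or len(alts[0]) != 1 or alts[0] not in "ACGT":
                n_non_snp += 1
                continue
            ad: dict[str, tuple[int, int]] = {}
            for sample in SAMPLES:
                values = rec.samples[sample].get("AD")
                if values is None or any(v is None for v in values):
                    raise VariantFormatError(
                        f"{rec.chrom}:{rec.pos}: sample {sample} has no AD"
                    )
                ad[sample] = (int(values[0]), int(values[1]))
            sites.append(SnpSite(rec.chrom, rec.pos, rec.ref, alts[0], ad))
    if n_multi or n_non_snp:
        logger.info(
            "skipped %d multiallelic and %d non-SNP records", n_multi, n_non_snp
        )
    return ParsedVariants(sites, n_multi, n_non_snp)


def sites_from_frame(table: pd.DataFrame) -> list[SnpSite]:
    """Build SnpSites from a simulator allelic-depth table (no VCF round trip)."""
    sites = []
    for row in table.itertuples(index=False):
        ad = {
            s: (int(getattr(row, f"{s}_ref")), int(getattr(row, f"{s}_alt")))
            for s in SAMPLES
        }
        sites.append(SnpSite(row.chrom, int(row.pos), row.ref, row.alt, ad))
    return sites


def parent_allele(site: SnpSite, parent: str) -> str | None:
    """Majority-read allele ('ref'/'alt') of a parent; None without coverage."""
    r, a = site.ad[parent]
    if r + a == 0:
        return None
    return "alt" if a >= r else "ref"


def compute_snp_index(site: SnpSite, high_parent: str) -> SnpIndexRecord:
    """SNP index of both bulks relative to the high parent's allele.

    index = (bulk reads carrying the high parent's allele) / (bulk depth).
    A bulk with zero depth yields index ``None`` and flag ``no-coverage``;
    an uncovered high parent yields flag ``no-parent-allele``.
    """
    if high_parent not in PARENTS:
        raise ValueError(f"high_parent must be one of {PARENTS}")
    allele = parent_allele(site, high_parent)
    flag = None
    indices: dict[str, float | None] = {}
    for bulk in BULKS:
        r, a = site.ad[bulk]
        depth = r + a
        if allele is None:
            indices[bulk] = None
            flag = "no-parent-allele"
        elif depth == 0:
            indices[bulk] = None
            flag = "no-coverage"
        else:
            reads = a if allele == "alt" else r
            indices[bulk] = reads / depth
    return SnpIndexRecord(
        site=site,
        high_parent=high_parent,
        index_by=indices["BY"],
        index_ky=indices["KY"],
        depth_by=site.depth("BY"),
        depth_ky=site.depth("KY"),
        flag=flag,
    )


@dataclass
class FilterResult:
    retained: list[SnpIndexRecord]
    tally: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + sum(self.tally.values())


#: rejection reasons, in the fixed order the checks are applied
FILTER_REASONS = ("parent", "depth", "low-index-both", "no-coverage")


def apply_filters(
    records: Iterable[SnpIndexRecord],
    min_depth: int = 7,
    low_index: float = 0.3,
    parent_tol: float = 0.1,
    het_rule: str = "parent",
) -> FilterResult:
    """Apply the site-quality filters, tallying rejections by reason.

    Checks, in order: (a) parent informativeness — under the default
    ``het_rule='parent'`` both parents must be covered, effectively
    homozygous (minor-read fraction <= ``parent_tol``) and carry different
    alleles; under ``het_rule='progeny'`` parents need only disagree in
    consensus, and sites looking heterozygous in *both* bulks (minor
    fraction > ``parent_tol``) are rejected instead; (b) depth <
    ``min_depth`` in either bulk; (c) SNP index < ``low_index`` in both
    bulks; (d) any remaining missing/no-coverage flag. Thresholds are
    strict inequalities.
    """
    if het_rule not in ("parent", "progeny"):
        raise ValueError("het_rule must be 'parent' or 'progeny'")
    retained: list[SnpIndexRecord] = []
    tally = {reason: 0 for reason in FILTER_REASONS}

    for rec in records:
        reason = _rejection_reason(rec, min_depth, low_index, parent_tol, het_rule)
        rec.passed = reason is None
        rec.reason = reason
        if reason is None:
            retained.append(rec)
        else:
            tally[reason] += 1
    return FilterResult(retained, tally)


def _rejection_reason(
    rec: SnpIndexRecord,
    min_depth: int,
    low_index: float,
    parent_tol: float,
    het_rule: str,
) -> str | None:
    site = rec.site
    # (a) parent informativeness
    alleles = {}
    for parent in PARENTS:
        r, a = site.ad[parent]
        depth = r + a
        if depth == 0:
            return "parent"
        minor = min(r, a) / depth
        if het_rule == "parent" and minor > parent_tol:
            return "parent"
        alleles[parent] = "alt" if a >= r else "ref"
    if alleles["XAP1"] == alleles["AYP1"]:
        return "parent"
    if het_rule == "progeny":
        minors = []
        for bulk in BULKS:
            r, a = site.ad[bulk]
            if r + a:
                minors.append(min(r, a) / (r + a))
        if len(minors) == 2 and all(m > parent_tol for m in minors):
            return "parent"
    # (b) bulk depth
    if rec.depth_by < min_depth or rec.depth_ky < min_depth:
        return "depth"
    # (c) low index in BOTH bulks
    if (
        rec.index_by is not None
        and rec.index_ky is not None
        and rec.index_by < low_index
        and rec.index_ky < low_index
    ):
        return "low-index-both"
    # (d) anything still flagged as missing
    if rec.index_by is None or rec.index_ky is None:
        return "no-coverage"
    return None


def records_to_frame(records: Iterable[SnpIndexRecord]) -> pd.DataFrame:
    """Retained-site table: chrom, pos, alleles, per-bulk depths and indices."""
    rows = []
    for rec in records:
        rows.append(
            {
                "chrom": rec.site.chrom,
                "pos": rec.site.pos,
                "ref": rec.site.ref_allele,
                "alt": rec.site.alt_allele,
                "high_parent": rec.high_parent,
                "depth_by": rec.depth_by,
                "depth_ky": rec.depth_ky,
                "index_by": rec.index_by,
                "index_ky": rec.index_ky,
            }
        )
    return pd.DataFrame(rows)


def write_filter_outputs(result: FilterResult, sites_path: str, tally_path: str) -> None:
    records_to_frame(result.retained).to_csv(sites_path, sep="\t", index=False)
    tally = pd.DataFrame(
        {"reason": list(result.tally), "n_rejected": list(result.tally.values())}
    )
    tally.to_csv(tally_path, sep="\t", index=False)
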