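"""Calling miRNA mutation/editing (M/E) sites from pre-miRNA alignments.

The caller works on per-sample pileups of small-RNA reads aligned to
pre-miRNA references.  For every covered position it tallies reads per
alternative nucleotide; an (alt, position) pair is a candidate M/E site.
The editing level of a site is the number of edited reads divided by
the total reads covering it.  Significance is assessed against the
sequencing-error null: under no editing, the count of a specific
alternative base at a position is binomial with per-base success
probability ``p_err / 3``, where ``p_err = 10**(-Q/10)`` for the Phred
quality floor Q applied upstream (Q30 by default, so 1e-3).  P-values
are corrected per sample with the Benjamini-Hochberg step-up and sites
are called when, within a sample,

* the editing level is at least ``min_level`` (default 5%),
* at least ``min_edited_reads`` reads support the edit (default 10), and
* the BH-adjusted p-value is below ``max_fdr`` (default 0.05).

The cohort-level site set is the union of sites significant in at least
one sample; levels are then reported for every sample, as missing (NaN)
where a sample has no coverage at the site.

A non-templated 3' addition (e.g. 3'-uridylation) is represented as a
substitution at the first reference position past the templated 3' end,
so a uridylated mature miRNA appears as, say, ``<pre-miR>_48_G_u``.

Site names follow the convention ``<pre-miR>_<pos>_<REF>_<alt>`` with
the reference base upper-case and the edited base lower-case; the
corresponding edited miRNA is ``<pre-miR>_<pos><alt>``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import RNA_ALPHABET, ParseError, SamRead


class SiteError(ValueError):
    """An invalid site definition or undefined quantity."""


@dataclasses.dataclass(frozen=True)
class PileupColumn:
    """Nucleotide tallies at one pre-miRNA position in one sample."""

    premirna: str
    position: int  # 1-based
    ref_nt: str
    counts: Mapping[str, int]  # alt nucleotide -> supporting reads
    total: int  # all reads covering the position

    def __post_init__(self) -> None:
        if self.position < 1:
            raise SiteError(f"position {self.position} < 1")
        if self.total < sum(self.counts.values()):
            raise SiteError(
                f"{self.premirna}:{self.position}: mismatch counts exceed coverage"
            )


@dataclasses.dataclass(frozen=True)
class EditingSite:
    premirna: str
    position: int
    ref_nt: str
    alt_nt: str
    edited_reads: int
    total_reads: int
    level: float
    pvalue: float
    qvalue: float
    site_name: str
    edited_mirna_name: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.premirna, self.position, self.ref_nt, self.alt_nt)


@dataclasses.dataclass(frozen=True)
class CallThresholds:
    min_level: float = 0.05
    min_edited_reads: int = 10
    phred_min: int = 30
    max_fdr: float = 0.05

    def __post_init__(self) -> None:
        if not 0 <= self.min_level <= 1:
            raise SiteError("min_level must be in [0, 1]")
        if self.min_edited_reads < 0:
            raise SiteError("min_edited_reads must be non-negative")
        if not 0 < self.max_fdr <= 1:
            raise SiteError("max_fdr must be in (0, 1]")

    @property
    def p_err(self) -> float:
        """Per-base sequencing-error probability implied by the Phred floor."""
        return 10.0 ** (-self.phred_min / 10.0)


def pileup_from_alignments(
    alignments: Iterable[SamRead], references: Mapping[str, str]
) -> list[PileupColumn]:
    """Tally one sample's alignments into per-position pileup columns.

    Only M operations consume the reference; soft clips consume query
    only.  Positions with no coverage are omitted.
    """
    totals: dict[tuple[str, int], int] = {}
    mismatches: dict[tuple[str, int], dict[str, int]] = {}
    for read in alignments:
        if read.rname not in references:
            raise ParseError(f"read {read.qname!r}: unknown reference {read.rname!r}")
        ref = references[read.rname]
        ops = read.cigar_ops()
        consumed = sum(length for _, length in ops)
        if consumed != len(read.seq):
            raise ParseError(
                f"read {read.qname!r}: CIGAR consumes {consumed} bases but "
                f"SEQ has {len(read.seq)}"
            )
        qpos = 0
        rpos = read.pos  # 1-based
        for op, length in ops:
            if op == "S":
                qpos += length
                continue
            for off in range(length):
                pos = rpos + off
                if pos > len(ref):
                    raise ParseError(
                        f"read {read.qname!r}: alignment runs past reference "
                        f"{read.rname!r} (length {len(ref)})"
                    )
                base = read.seq[qpos + off]
                key = (read.rname, pos)
                totals[key] = totals.get(key, 0) + 1
                if base != ref[pos - 1]:
                    mismatches.setdefault(key, {}).setdefault(base, 0)
                    mismatches[key][base] += 1
            qpos += length
            rpos += length

    columns = [
        PileupColumn(
            premirna=name,
            position=pos,
            ref_nt=references[name][pos - 1],
            counts=dict(sorted(mismatches.get((name, pos), {}).items())),
            total=total,
        )
        for (name, pos), total in sorted(totals.items())
    ]
    return columns


def editing_level(edited_reads: int, total_reads: int) -> float:
    """Edited reads over total reads covering the site."""
    if total_reads < 1:
        raise SiteError("editing level undefined for zero coverage")
    if not 0 <= edited_reads <= total_reads:
        raise SiteError("edited_reads must be within [0, total_reads]")
    return edited_reads / total_reads


def site_pvalue(edited_reads: int, total_reads: int, p_err: float) -> float:
    """Upper-tail binomial probability of >= edited_reads errors.

    ``p_err`` is the probability that a read shows this specific
    alternative base by sequencing error alone.
    """
    if not 0 < p_err < 1:
        raise SiteError("p_err must be in (0, 1)")
    if not 0 <= edited_reads <= total_reads:
        raise SiteError("edited_reads must be within [0, total_reads]")
    if edited_reads == 0:
        return 1.0
    return float(stats.binom.sf(edited_reads - 1, total_reads, p_err))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise SiteError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise SiteError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def name_me_site(
    premirna: str, position: int, ref_nt: str, alt_nt: str
) -> tuple[str, str]:
    """Name an M/E site and its edited miRNA.

    The reference base is upper-case and the edited base lower-case,
    e.g. ``hsa-mir-497_25_A_g`` with edited miRNA ``hsa-mir-497_25g``.
    """
    ref = ref_nt.upper()
    alt = alt_nt.upper()
    if ref not in RNA_ALPHABET or alt not in RNA_ALPHABET:
        raise SiteError(f"invalid nucleotides {ref_nt!r}/{alt_nt!r}")
    if ref == alt:
        raise SiteError("reference and alternative nucleotides are equal")
    site_name = f"{premirna}_{position}_{ref}_{alt.lower()}"
    edited_name = f"{premirna}_{position}{alt.lower()}"
    return site_name, edited_name


def parse_me_site_name(site_name: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`name_me_site` for the site name."""
    parts = site_name.rsplit("_", 3)
    if len(parts) != 4:
        raise SiteError(f"malformed site name {site_name!r}")
    premirna, pos, ref, alt = parts
    if not pos.isdigit() or ref.upper() not in RNA_ALPHABET or alt.upper() not in RNA_ALPHABET:
        raise SiteError(f"malformed site name {site_name!r}")
    return premirna, int(pos), ref.upper(), alt.upper()


def edited_mirna_sequence(
    premirna_seq: str,
    mature_start: int,
    mature_end: int,
    position: int,
    alt_nt: str,
) -> str:
    """Emit the edited mature sequence with the edit lower-cased.

    ``position`` is 1-based on the pre-miRNA.  Positions inside the
    mature window substitute; position ``mature_end + 1`` appends one
    non-templated (3'-added) nucleotide.
    """
    if not 1 <= mature_start <= mature_end <= len(premirna_seq):
        raise SiteError("mature window outside pre-miRNA")
    alt = alt_nt.upper()
    if alt not in RNA_ALPHABET:
        raise SiteError(f"invalid nucleotide {alt_nt!r}")
    mature = premirna_seq[mature_start - 1 : mature_end].upper()
    if mature_start <= position <= mature_end:
        off = position - mature_start
        return mature[:off] + alt.lower() + mature[off + 1 :]
    if position == mature_end + 1:
        return mature + alt.lower()
    raise SiteError(
        f"position {position} outside mature window "
        f"[{mature_start}, {mature_end + 1}]"
    )


@dataclasses.dataclass
class CallResult:
    """Per-sample calls plus the cohort union of significant sites."""

    per_sample: dict[str, list[EditingSite]]
    union: list[tuple[str, int, str, str]]  # (premirna, position, ref, alt)
    levels: pd.DataFrame  # samples x union site names; NaN where uncovered


def _sample_sites(pileups: Sequence[PileupColumn], p_alt: float) -> list[EditingSite]:
    """Score every candidate (position, alt) with >= 1 supporting read."""
    cands: list[tuple[PileupColumn, str, int]] = []
    for col in pileups:
        for alt, k in col.counts.items():
            if k >= 1:
                cands.append((col, alt, k))
    if not cands:
        return []
    pvals = np.array([site_pvalue(k, col.total, p_alt) for col, _, k in cands])
    qvals = bh_adjust(pvals)
    sites = []
    for (col, alt, k), p, q in zip(cands, pvals, qvals):
        site_name, edited_name = name_me_site(col.premirna, col.position, col.ref_nt, alt)
        sites.append(
            EditingSite(
                premirna=col.premirna,
                position=col.position,
                ref_nt=col.ref_nt,
                alt_nt=alt,
                edited_reads=k,
                total_reads=col.total,
                level=editing_level(k, col.total),
                pvalue=float(p),
                qvalue=float(q),
                site_name=site_name,
                edited_mirna_name=edited_name,
            )
        )
    return sites


def is_significant(site: EditingSite, thresholds: CallThresholds) -> bool:
    return (
        site.level >= thresholds.min_level
        and site.edited_reads >= thresholds.min_edited_reads
        and site.qvalue < thresholds.max_fdr
    )


def call_sites(
    pileups_by_sample: Mapping[str, Sequence[PileupColumn]],
    thresholds: CallThresholds | None = None,
    p_err: float | None = None,
) -> CallResult:
    """Call M/E sites per sample and form the cohort union.

    ``p_err`` defaults to the rate implied by ``thresholds.phred_min``;
    the null for a specific alternative base uses ``p_err / 3`` since an
    error is equally likely to produce any of the three non-reference
    bases.  BH adjustment is per sample, across that sample's candidate
    sites.  The union keeps sites significant in at least one sample and
    reports levels for every sample, NaN where a sample lacks coverage.
    """
    thresholds = thresholds or CallThresholds()
    p_alt = (p_err if p_err is not None else thresholds.p_err) / 3.0

    per_sample: dict[str, list[EditingSite]] = {}
    for sample, pileups in pileups_by_sample.items():
        per_sample[sample] = _sample_sites(pileups, p_alt)

    union_keys = sorted(
        {
            site.key
            for sites in per_sample.values()
            for site in sites
            if is_significant(site, thresholds)
        }
    )

    coverage: dict[str, dict[tuple[str, int], PileupColumn]] = {
        sample: {(c.premirna, c.position): c for c in pileups}
        for sample, pileups in pileups_by_sample.items()
    }
    names = [name_me_site(*key)[0] for key in union_keys]
    levels = pd.DataFrame(
        np.nan, index=list(pileups_by_sample), columns=names, dtype=float
    )
    levels.index.name = "sample"
    for j, key in enumerate(union_keys):
        premirna, pos, _, alt = key
        for sample in pileups_by_sample:
            col = coverage[sample].get((premirna, pos))
            if col is not None and col.total > 0:
                levels.iloc[levels.index.get_loc(sample), j] = editing_level(
                    col.counts.get(alt, 0), col.total
                )
    return CallResult(per_sample=per_sample, union=union_keys, levels=levels)


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    """Tabulate called sites for TSV export."""
    return pd.DataFrame(
        [
            {
                "site_name": s.site_name,
                "edited_mirna_name": s.edited_mirna_name,
                "premirna": s.premirna,
                "position": s.position,
                "ref_nt": s.ref_nt,
                "alt_nt": s.alt_nt,
                "level": s.level,
                "edited_reads": s.edited_reads,
                "total_reads": s.total_reads,
                "pvalue": s.pvalue,
                "qvalue": s.qvalue,
            }
            for s in sites
        ]
    )
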