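"""Synthetic small-RNA cohorts with known ground truth.

Two independent generators are provided:

* :func:`simulate_pileup_cohort` emits per-sample SAM-lite alignments of
  reads against randomly drawn pre-miRNA references, with editing events
  planted at chosen sites and a uniform per-base sequencing-error rate.
  Read depth per (sample, pre-miRNA) is negative-binomial, matching the
  overdispersion of real small-RNA libraries.  The default error rate of
  1e-3 corresponds to a Phred-30 quality floor.

* :func:`simulate_feature_cohort` emits a two-class, multi-batch cohort
  of feature matrices directly: negative-binomial counts for original
  (AOM) and edited (AEM) miRNAs with per-sample library-size factors and
  per-batch log-scale shifts, and beta-distributed editing levels (EL)
  on the 0..1 scale.  Class effects are planted as log2 fold changes
  (counts) or editing-level differences (EL).

The defaults of :class:`CohortSimConfig` mirror the study design this
package targets: five batches, two classes of roughly equal size
(198 + 198 samples, close to the 395-sample tumor/control cohort), and
feature families sized like the filtered analysis matrices (422 AOM,
957 AEM, 1221 EL).  Tests and examples scale these down for speed.

Every generator consumes a single seeded :class:`numpy.random.Generator`
stream, so identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io import RNA_ALPHABET, SamRead

CLASS_CASE = "LUAD"
CLASS_CONTROL = "CTL"


class ConfigError(ValueError):
    """An invalid simulation configuration."""


@dataclasses.dataclass(frozen=True)
class PlantedSite:
    """An editing event planted at one pre-miRNA position.

    ``position`` is 1-based on the pre-miRNA.  A position one past the
    mature 3' end models a non-templated 3' addition.  ``level`` is the
    per-read probability of carrying the edit.
    """

    premirna: str
    position: int
    ref_nt: str
    alt_nt: str
    level: float


@dataclasses.dataclass(frozen=True)
class PlantedEffect:
    """A class-discriminative effect on one feature.

    For count features (kind AOM/AEM) ``effect`` is the log2 fold change
    applied to the case-class mean; for EL features it is an additive
    editing-level difference on the 0..1 scale.
    """

    feature: str
    kind: str  # AOM | AEM | EL
    effect: float


@dataclasses.dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated dataset."""

    planted_sites: list[PlantedSite] = dataclasses.field(default_factory=list)
    planted_effects: list[PlantedEffect] = dataclasses.field(default_factory=list)
    samples: pd.DataFrame | None = None  # index sample; columns batch, class


@dataclasses.dataclass(frozen=True)
class PileupSimConfig:
    n_premirnas: int = 20
    premirna_length: int = 70
    mature_window: tuple[int, int] = (25, 46)  # 1-based inclusive, 22 nt
    coverage_mean: float = 200.0
    coverage_dispersion: float = 5.0  # NB size; var = mu + mu^2/size
    planted_sites: tuple[PlantedSite, ...] = ()
    seq_error_rate: float = 1e-3  # Phred 30
    n_samples: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.seq_error_rate < 1:
            raise ConfigError("seq_error_rate must be in [0, 1)")
        if self.coverage_dispersion <= 0:
            raise ConfigError("coverage_dispersion must be positive")
        lo, hi = self.mature_window
        if not 1 <= lo <= hi <= self.premirna_length:
            raise ConfigError("mature_window outside pre-miRNA")
        for site in self.planted_sites:
            if not 0 <= site.level <= 1:
                raise ConfigError(f"planted level {site.level} outside [0, 1]")
            if not 1 <= site.position <= self.premirna_length:
                raise ConfigError(
                    f"planted position {site.position} outside pre-miRNA "
                    f"of length {self.premirna_length}"
                )
            if site.ref_nt == site.alt_nt:
                raise ConfigError("planted ref and alt nucleotides are equal")


@dataclasses.dataclass(frozen=True)
class CohortSimConfig:
    n_per_class: int = 198
    n_batches: int = 5
    batch_assignment: tuple[float, ...] | None = None  # proportions, default equal
    n_aom: int = 422
    n_aem: int = 957
    n_el: int = 1221
    planted_effects: tuple[PlantedEffect, ...] = ()
    nb_mean_range: tuple[float, float] = (20.0, 500.0)
    nb_dispersion: float = 2.0  # NB size; var = mu + mu^2/size
    libsize_log_sd: float = 0.3
    batch_logshift_sd: float = 0.5
    el_beta_concentration: float = 30.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 2:
            raise ConfigError("need at least 2 samples per class")
        if self.n_batches < 1:
            raise ConfigError("need at least one batch")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.batch_assignment is not None and len(self.batch_assignment) != self.n_batches:
            raise ConfigError("batch_assignment length must equal n_batches")
        ids = set(aom_feature_ids(self.n_aom)) | set(aem_feature_ids(self.n_aem)) | set(
            el_feature_ids(self.n_el)
        )
        for eff in self.planted_effects:
            if eff.feature not in ids:
                raise ConfigError(f"planted feature {eff.feature!r} does not exist")
            if eff.kind not in ("AOM", "AEM", "EL"):
                raise ConfigError(f"unknown feature kind {eff.kind!r}")


def aom_feature_ids(n: int) -> list[str]:
    """Synthetic original-miRNA names (mature 5p arms)."""
    return [f"syn-miR-{i:04d}-5p" for i in range(n)]


def aem_feature_ids(n: int) -> list[str]:
    """Synthetic edited-miRNA names following the <pre-miR>_<pos><alt> scheme."""
    return [f"syn-mir-{i:04d}_25g" for i in range(n)]


def el_feature_ids(n: int) -> list[str]:
    """Synthetic editing-site names following <pre-miR>_<pos>_<REF>_<alt>."""
    return [f"syn-mir-{i:04d}_25_A_g" for i in range(n)]


def _premirna_names(n: int) -> list[str]:
    return [f"syn-mir-{i:04d}" for i in range(n)]


def simulate_pileup_cohort(
    cfg: PileupSimConfig,
) -> tuple[dict[str, list[SamRead]], dict[str, str], TruthTable]:
    """Simulate per-sample SAM-lite alignments against pre-miRNA references.

    Reads cover the mature window of each pre-miRNA.  A read carrying a
    planted 3'-addition (position = mature end + 1) is emitted one base
    longer than the templated mature sequence.  Sequencing errors are
    applied after planting, each erroneous base replaced uniformly by
    one of the three alternative nucleotides.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = _premirna_names(cfg.n_premirnas)
    alpha = np.array(RNA_ALPHABET)

    refs: dict[str, str] = {}
    ref_codes: dict[str, np.ndarray] = {}
    for name in names:
        codes = rng.integers(0, 4, size=cfg.premirna_length)
        ref_codes[name] = codes
        refs[name] = "".join(alpha[codes])

    planted_by_mir: dict[str, list[PlantedSite]] = {}
    for site in cfg.planted_sites:
        if site.premirna not in refs:
            raise ConfigError(f"planted pre-miRNA {site.premirna!r} does not exist")
        # force the stated reference base at the planted position
        codes = ref_codes[site.premirna]
        codes[site.position - 1] = RNA_ALPHABET.index(site.ref_nt)
        refs[site.premirna] = "".join(alpha[codes])
        planted_by_mir.setdefault(site.premirna, []).append(site)

    lo, hi = cfg.mature_window
    read_len = hi - lo + 1
    size = cfg.coverage_dispersion
    p_nb = size / (size + cfg.coverage_mean)

    sample_ids = [f"S{idx:04d}" for idx in range(cfg.n_samples)]
    reads_by_sample: dict[str, list[SamRead]] = {}
    for sample in sample_ids:
        reads: list[SamRead] = []
        for name in names:
            codes = ref_codes[name]
            depth = int(rng.negative_binomial(size, p_nb))
            if depth == 0:
                continue
            window = np.tile(codes[lo - 1 : hi], (depth, 1))
            tail_alt: np.ndarray | None = None
            for site in planted_by_mir.get(name, ()):
                edited = rng.random(depth) < site.level
                alt_code = RNA_ALPHABET.index(site.alt_nt)
                if lo <= site.position <= hi:
                    window[edited, site.position - lo] = alt_code
                elif site.position == hi + 1:
                    tail_alt = np.where(edited, alt_code, -1)
                # planted positions outside the read window are silent
            if cfg.seq_error_rate > 0:
                err = rng.random(window.shape) < cfg.seq_error_rate
                # uniform choice among the 3 alternative bases
                shift = rng.integers(1, 4, size=window.shape)
                window = np.where(err, (window + shift) % 4, window)
            for i in range(depth):
                seq = "".join(alpha[window[i]])
                if tail_alt is not None and tail_alt[i] >= 0:
                    base = alpha[tail_alt[i]]
                    if cfg.seq_error_rate > 0 and rng.random() < cfg.seq_error_rate:
                        base = alpha[(tail_alt[i] + rng.integers(1, 4)) % 4]
                    seq += base
                    cigar = f"{read_len + 1}M"
                else:
                    cigar = f"{read_len}M"
                reads.append(
                    SamRead(
                        qname=f"{sample}:{name}:{i}",
                        rname=name,
                        pos=lo,
                        cigar=cigar,
                        seq=seq,
                    )
                )
        reads_by_sample[sample] = reads

    truth = TruthTable(
        planted_sites=list(cfg.planted_sites),
        samples=pd.DataFrame(index=pd.Index(sample_ids, name="sample")),
    )
    return reads_by_sample, refs, truth


def _allocate_batches(n: int, proportions: Sequence[float]) -> np.ndarray:
    """Largest-remainder allocation of n samples to batches."""
    props = np.asarray(proportions, dtype=float)
    props = props / props.sum()
    raw = props * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    out = np.repeat(np.arange(len(props)), base)
    return out


def simulate_feature_cohort(
    cfg: CohortSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate (AOM counts, AEM counts, EL levels, metadata, truth).

    Matrices are samples x features.  Counts follow a negative-binomial
    model ``mu[s, f] = mu_f * 2^(effect * is_case) * libsize_s *
    exp(batchshift[b(s), f])``; editing levels follow per-sample beta
    draws around a per-feature mean, shifted additively for planted EL
    effects in the case class.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = 2 * cfg.n_per_class
    sample_ids = [f"S{idx:04d}" for idx in range(n)]
    classes = np.array([CLASS_CASE] * cfg.n_per_class + [CLASS_CONTROL] * cfg.n_per_class)

    props = cfg.batch_assignment or tuple([1.0 / cfg.n_batches] * cfg.n_batches)
    # interleave classes before batch assignment so batches mix classes
    order = rng.permutation(n)
    batch_of = np.empty(n, dtype=int)
    batch_of[order] = _allocate_batches(n, props)
    meta = pd.DataFrame(
        {
            "batch": [f"batch{b + 1}" for b in batch_of],
            "class": classes,
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    is_case = (classes == CLASS_CASE).astype(float)
    libsize = np.exp(rng.normal(0.0, cfg.libsize_log_sd, size=n))

    effects = {(e.kind, e.feature): e.effect for e in cfg.planted_effects}

    def _count_matrix(ids: list[str], kind: str) -> pd.DataFrame:
        p = len(ids)
        log_lo, log_hi = np.log(cfg.nb_mean_range[0]), np.log(cfg.nb_mean_range[1])
        mu = np.exp(rng.uniform(log_lo, log_hi, size=p))
        shifts = rng.normal(0.0, cfg.batch_logshift_sd, size=(cfg.n_batches, p))
        l2fc = np.array([effects.get((kind, f), 0.0) for f in ids])
        mean = (
            mu[None, :]
            * np.exp2(np.outer(is_case, l2fc))
            * libsize[:, None]
            * np.exp(shifts[batch_of, :])
        )
        size = cfg.nb_dispersion
        counts = rng.negative_binomial(size, size / (size + mean))
        return pd.DataFrame(counts, index=sample_ids, columns=ids)

    aom = _count_matrix(aom_feature_ids(cfg.n_aom), "AOM")
    aem = _count_matrix(aem_feature_ids(cfg.n_aem), "AEM")

    el_ids = el_feature_ids(cfg.n_el)
    base_mean = np.clip(rng.beta(1.2, 6.0, size=cfg.n_el), 0.01, 0.95)
    delta = np.array([effects.get(("EL", f), 0.0) for f in el_ids])
    el_mean = np.clip(base_mean[None, :] + np.outer(is_case, delta), 0.005, 0.995)
    conc = cfg.el_beta_concentration
    el = rng.beta(el_mean * conc, (1.0 - el_mean) * conc)
    el = pd.DataFrame(el, index=sample_ids, columns=el_ids)

    truth = TruthTable(planted_effects=list(cfg.planted_effects), samples=meta.copy())
    return aom, aem, el, meta, truth
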