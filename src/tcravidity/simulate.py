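"""Synthetic TCR panels, exposure profiles, contact tables and repertoires.

Every downstream stage of the pipeline is validated by parameter recovery on
data with known planted structure, generated here:

* **Panels** of clonotypes with class-conditional CDR3b composition — high-
  avidity sequences draw letters from a mixture tilted toward an enrichment
  set (default {N, E, I, K, T, Y, V}) and low-avidity sequences toward a
  depletion set (default {A, R, D, L, M, P}), mirroring the amino-acid
  enrichment observed between avidity classes. The mixing weight (default
  0.35) produces a detectable but imperfect signal: the real effect is an
  enrichment, not a deterministic rule.
* **Exposure profiles** with i.i.d. per-position exposed/buried draws, and an
  optional coupled mode where enrichment-set letters are exposed more often —
  the regime in which exposure-gated features carry recoverable signal.
* **Contact tables** satisfying T1/2 = K + gamma*n_apolar + delta*n_polar
  plus Gaussian noise, exactly linear when the noise SD is zero.
* **Paired blood/tumor repertoires** multinomially sampled from a panel with
  a configurable odds multiplier favouring high-avidity clonotypes in the
  tumor compartment only (multiplier 1 = exchangeable compartments).

Identical spec + seed reproduces byte-identical output. The generator plants
composition, exposure and linear structure only; it does not model V(D)J
recombination, germline genes, or real repertoire clone-size laws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import AA_ALPHABET, ContactCounts, ExposureProfile, TcrClonotype

#: Letters enriched in high-avidity CDR3b sequences (default planting set).
DEFAULT_ENRICHMENT_RESIDUES = ("N", "E", "I", "K", "T", "Y", "V")
#: Letters more frequent in low-avidity CDR3b sequences.
DEFAULT_DEPLETION_RESIDUES = ("A", "R", "D", "L", "M", "P")


@dataclass
class PanelSpec:
    """Recipe for a synthetic clone panel with planted composition signal.

    Defaults emulate the dimensions of the curated training panel: 48
    clonotypes of which 11 are high avidity (half-life > 60 s), CDR3b lengths
    11-20, 12 distinct cognate pMHCs. Half-lives are drawn uniformly from a
    class interval; the low interval (2-55 s) deliberately spans the 10 s
    intermediate-avidity boundary so the clustering hotspot analysis sees all
    three avidity bands, and neither interval straddles the 60 s class
    boundary.
    """

    n_tcrs: int = 48
    cdr3_length_range: tuple[int, int] = (11, 20)
    high_fraction: float = 11 / 48
    enrichment_residues: tuple[str, ...] = DEFAULT_ENRICHMENT_RESIDUES
    depletion_residues: tuple[str, ...] = DEFAULT_DEPLETION_RESIDUES
    enrichment_weight: float = 0.35
    halflife_ranges: tuple[tuple[float, float], tuple[float, float]] = (
        (2.0, 55.0),
        (65.0, 180.0),
    )
    exposure_rate: float = 0.5
    coupled_exposure: bool = False
    coupled_exposure_rate: float = 0.85
    motif: Optional[str] = None
    motif_rate: float = 0.9
    n_epitopes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tcrs < 0:
            raise ValueError("n_tcrs must be nonnegative")
        lo, hi = self.cdr3_length_range
        if lo < 11:
            raise ValueError(
                "minimum CDR3b length must be at least 11 (shorter sequences "
                "have no 4-mer subunit)"
            )
        if hi < lo:
            raise ValueError("cdr3_length_range must be (min, max) with min <= max")
        if not 0.0 <= self.high_fraction <= 1.0:
            raise ValueError("high_fraction must lie in [0, 1]")
        (low_lo, low_hi), (high_lo, high_hi) = self.halflife_ranges
        if not (low_lo <= low_hi < 60.0):
            raise ValueError("low half-life interval must lie strictly below 60 s")
        if not (60.0 < high_lo <= high_hi):
            raise ValueError("high half-life interval must lie strictly above 60 s")
        if not 0.0 <= self.exposure_rate <= 1.0:
            raise ValueError("exposure_rate must lie in [0, 1]")
        for r in self.enrichment_residues + self.depletion_residues:
            if r not in AA_ALPHABET:
                raise ValueError(f"unknown residue {r!r} in planting sets")
        if self.motif is not None and (
            len(self.motif) != 4 or any(c not in AA_ALPHABET for c in self.motif)
        ):
            raise ValueError("motif must be a 4-mer over the amino-acid alphabet")


@dataclass
class ContactSpec:
    """Recipe for a synthetic contact-count table with planted linear structure."""

    n_complexes: int = 10
    k: float = -62.89
    gamma: float = 2.647
    delta: float = 8.747
    noise_sd: float = 0.0
    apolar_range: tuple[int, int] = (20, 45)
    polar_range: tuple[int, int] = (2, 12)
    clip_negative: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_complexes < 0:
            raise ValueError("n_complexes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("apolar_range", "polar_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must be a nonnegative (min, max) interval")


def _draw_sequence(
    rng: np.random.Generator,
    length: int,
    favored: Sequence[str],
    weight: float,
) -> str:
    """CDR3b with conserved 'CASS' lead, favored-mixture core, and a short
    junction-like tail ending in F. Only the core (the region contributing
    4-mer subunits) carries the planted composition."""
    core_len = length - 7
    core = []
    for _ in range(core_len):
        if favored and rng.random() < weight:
            core.append(favored[rng.integers(len(favored))])
        else:
            core.append(AA_ALPHABET[rng.integers(20)])
    tail = [AA_ALPHABET[rng.integers(20)], AA_ALPHABET[rng.integers(20)], "F"]
    return "CASS" + "".join(core) + "".join(tail)


def generate_panel(
    spec: PanelSpec,
) -> tuple[list[TcrClonotype], list[ExposureProfile]]:
    """Generate a labeled clone panel and one exposure profile per clonotype.

    Exactly ``round(n_tcrs * high_fraction)`` clonotypes are high avidity,
    listed first. Exposure masks are i.i.d. Bernoulli per position at
    ``exposure_rate`` (exposed positions draw a fraction in (0.30, 1], buried
    positions in [0, 0.30)); with ``coupled_exposure`` the Bernoulli rate for
    enrichment-set letters rises to ``coupled_exposure_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n_high = int(round(spec.n_tcrs * spec.high_fraction))
    lo_len, hi_len = spec.cdr3_length_range
    (low_t, high_t) = spec.halflife_ranges
    clonotypes: list[TcrClonotype] = []
    profiles: list[ExposureProfile] = []
    for i in range(spec.n_tcrs):
        is_high = i < n_high
        length = int(rng.integers(lo_len, hi_len + 1))
        favored = spec.enrichment_residues if is_high else spec.depletion_residues
        seq = _draw_sequence(rng, length, favored, spec.enrichment_weight)
        if is_high and spec.motif is not None and rng.random() < spec.motif_rate:
            # plant a shared central 4-mer so high-avidity TCRs form a clade
            start = int(rng.integers(4, length - 6))
            seq = seq[:start] + spec.motif + seq[start + 4 :]
        lo_t, hi_t = high_t if is_high else low_t
        halflife = float(rng.uniform(lo_t, hi_t))
        tcr_id = f"TCR{i + 1:03d}"
        clonotypes.append(
            TcrClonotype(
                tcr_id=tcr_id,
                cdr3b=seq,
                pmhc=f"pMHC{int(rng.integers(spec.n_epitopes)) + 1:02d}",
                halflife_s=halflife,
            )
        )
        rates = np.full(length, spec.exposure_rate)
        if spec.coupled_exposure:
            for pos, ch in enumerate(seq):
                if ch in spec.enrichment_residues:
                    rates[pos] = spec.coupled_exposure_rate
        exposed = rng.random(length) < rates
        fractions = np.where(
            exposed,
            rng.uniform(0.31, 1.0, size=length),
            rng.uniform(0.0, 0.29, size=length),
        )
        profiles.append(ExposureProfile(tcr_id=tcr_id, exposed_fraction=fractions))
    return clonotypes, profiles


def generate_feature_coupled_panel(
    spec: PanelSpec,
    weights: Optional[Mapping[str, float]] = None,
    n_label_flips: int = 2,
) -> tuple[list[TcrClonotype], list[ExposureProfile]]:
    """Panel whose avidity labels derive from exposure-gated CDR3b features.

    Emulates the near-separable regime of a curated training panel: sequences
    and exposure profiles are generated as in :func:`generate_panel`, each
    clonotype is scored by a planted linear model on its exposed-presence
    features (default weights on the canonical residue set {R, N, D, G, I, L,
    F}: positive for N, G, I, F and negative for R, D, L), and the
    ``round(n_tcrs * high_fraction)`` top-scoring clonotypes are labelled
    high avidity. ``n_label_flips`` boundary violations are then introduced
    (alternately one high-to-low and one low-to-high flip, uniformly chosen),
    so a refit classifier faces a small irreducible error — mirroring panels
    where the best model still makes one false positive and one false
    negative. Half-lives are finally drawn from the class intervals.

    Sequence composition is NOT class-coupled here (the label signal lives
    entirely in the exposure-gated features), so ``enrichment_weight`` is
    ignored; same spec + seed reproduces byte-identical output.
    """
    if weights is None:
        weights = {"R": -2.0, "N": 3.0, "D": -2.0, "G": 2.0, "I": 3.0, "L": -2.0, "F": 2.0}
    base = replace(spec, high_fraction=0.0, motif=None)
    clonotypes, profiles = generate_panel(base)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    residues = tuple(weights)
    scores = np.empty(len(clonotypes))
    for i, (c, prof) in enumerate(zip(clonotypes, profiles)):
        exposed = prof.exposed_fraction > 0.30
        feats = [
            1.0 if any(ch == r and exposed[j] for j, ch in enumerate(c.cdr3b)) else 0.0
            for r in residues
        ]
        scores[i] = float(np.dot(list(weights.values()), feats))
    scores += rng.normal(0.0, 1e-9, size=len(scores))  # deterministic tie-break
    n_high = int(round(spec.n_tcrs * spec.high_fraction))
    order = np.argsort(-scores)
    labels = np.zeros(len(clonotypes), dtype=bool)
    labels[order[:n_high]] = True
    for flip in range(min(n_label_flips, len(clonotypes))):
        pool = np.where(labels)[0] if flip % 2 == 0 else np.where(~labels)[0]
        if len(pool) == 0:
            continue
        idx = int(pool[rng.integers(len(pool))])
        labels[idx] = not labels[idx]
    (low_t, high_t) = spec.halflife_ranges
    for c, is_high in zip(clonotypes, labels):
        lo, hi = high_t if is_high else low_t
        c.halflife_s = float(rng.uniform(lo, hi))
    return clonotypes, profiles


def generate_contacts(spec: ContactSpec) -> list[ContactCounts]:
    """Contact tables obeying the planted linear half-life law plus noise.

    With ``noise_sd == 0`` every record satisfies the law exactly. Records
    may have negative half-life unless ``clip_negative`` is set — fitting is
    unconstrained, so clipping is off by default.
    """
    rng = np.random.default_rng(spec.seed)
    records = []
    for i in range(spec.n_complexes):
        n_apolar = int(rng.integers(spec.apolar_range[0], spec.apolar_range[1] + 1))
        n_polar = int(rng.integers(spec.polar_range[0], spec.polar_range[1] + 1))
        t = spec.k + spec.gamma * n_apolar + spec.delta * n_polar
        if spec.noise_sd > 0:
            t += float(rng.normal(0.0, spec.noise_sd))
        if spec.clip_negative:
            t = max(t, 0.0)
        records.append(
            ContactCounts(
                complex_id=f"CPLX{i + 1:03d}",
                n_apolar=n_apolar,
                n_polar=n_polar,
                halflife_s=t,
            )
        )
    return records


@dataclass
class RepertoireSample:
    """One bulk beta-chain repertoire: clonotype rows with read counts."""

    compartment: str  # "blood" | "tumor"
    table: pd.DataFrame = field(repr=False)  # columns cdr3_aa, count
    patient_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.compartment not in ("blood", "tumor"):
            raise ValueError("compartment must be 'blood' or 'tumor'")
        if not {"cdr3_aa", "count"}.issubset(self.table.columns):
            raise ValueError("repertoire table needs columns cdr3_aa, count")


def generate_repertoires(
    panel: Sequence[TcrClonotype],
    tumor_high_bias: float = 3.0,
    depth: int = 10_000,
    seed: int = 0,
    patient_id: str = "synthetic",
) -> tuple[RepertoireSample, RepertoireSample]:
    """Sample paired blood and tumor bulk repertoires from a labeled panel.

    Both compartments share a lognormal base abundance per clonotype; in the
    tumor the sampling weight of high-avidity clonotypes (half-life > 60 s)
    is multiplied by ``tumor_high_bias``. Reads are multinomial at the given
    depth; clonotypes receiving zero reads are dropped. A bias of 1 makes the
    compartments exchangeable.
    """
    if not panel:
        raise ValueError("panel must be nonempty")
    if depth <= 0:
        raise ValueError("sequencing depth must be positive")
    if tumor_high_bias <= 0:
        raise ValueError("tumor_high_bias must be positive")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=len(panel))
    high = np.array([bool(c.is_high_avidity) for c in panel])
    out = []
    for compartment in ("blood", "tumor"):
        weights = base.copy()
        if compartment == "tumor":
            weights[high] *= tumor_high_bias
        counts = rng.multinomial(depth, weights / weights.sum())
        keep = counts > 0
        table = pd.DataFrame(
            {
                "cdr3_aa": [c.cdr3b for i, c in enumerate(panel) if keep[i]],
                "v_gene": [c.v_gene or "" for i, c in enumerate(panel) if keep[i]],
                "j_gene": [c.j_gene or "" for i, c in enumerate(panel) if keep[i]],
                "count": counts[keep],
            }
        )
        out.append(
            RepertoireSample(compartment=compartment, table=table, patient_id=patient_id)
        )
    return out[0], out[1]
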