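"""Synthetic repertoires, expression matrices, and clinical cohorts with
known ground truth.

The generator emulates the statistical structure of a bulk-RNA-seq tumor
cohort with assembled BCR repertoires:

* clone frequencies drawn from a symmetric Dirichlet(alpha) — small alpha
  gives clonally restricted repertoires, large alpha near-uniform ones —
  with read counts multinomial over those frequencies;
* clone sequences derived from a germline V gene by i.i.d. substitutions at
  a per-base rate mu (substitution-only, so the germline-identity oracle is
  exact; indels are available behind a flag);
* overall survival exponential with hazard h0 * exp(beta * z) where z is
  the cohort-standardized species evenness, plus independent exponential
  censoring calibrated to a target censoring fraction;
* therapy response linked to BCR presence: non-responders lack an
  assembled IGHG repertoire more often than responders;
* class-structured log2 expression: each class shifts its marker genes by
  an effect size delta over i.i.d. Gaussian noise.

Randomness: one child RNG stream per sample is spawned from the master
seed, so per-sample draws are stable under reordering or parallel
generation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .types import ClinicalRecord, CloneRecord, GermlineReference, Repertoire
from . import diversity

__all__ = ["SimConfig", "SimTruth", "bundled_germline", "simulate_repertoire",
           "simulate_cohort", "simulate_expression"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Generator parameters; the defaults describe a melanoma-like bulk
    RNA-seq cohort with an IGHG-dominated, moderately clonal repertoire."""

    n_samples: int = 100
    chains: tuple[str, ...] = ("IGHG",)
    n_clones: tuple[int, int] = (5, 80)  # uniform range per sample
    dirichlet_alpha: float = 0.3
    total_reads: int = 8301  # median clone reads per sample
    total_reads_sdlog: float = 1.0  # log-normal spread of per-sample totals
    library_size: int = 50_000_000
    shm_rate: float = 0.04  # per-base substitution rate vs germline
    indel_rate: float = 0.0  # per-base indel rate (off by default)
    germline_length: int = 300
    n_germline: int = 3
    # survival: exponential baseline, log-hazard beta per SD of evenness
    baseline_hazard: float = math.log(2) / 2000.0  # median OS ~2000 days
    beta_evenness: float = math.log(1.38)
    censoring_rate: float = 0.5
    # response model
    responder_fraction: float = 0.3
    p_absent_nonresponder: float = 0.5
    p_absent_responder: float = 0.1
    # expression generator
    n_genes: int = 2000
    n_classes: int = 3
    markers_per_class: int = 40
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dirichlet_alpha <= 0 or self.shm_rate < 0 or self.noise_sd <= 0:
            raise ValueError("rates and SDs must be positive")
        if self.total_reads_sdlog < 0:
            raise ValueError("total_reads_sdlog must be non-negative")
        for p in (self.censoring_rate, self.responder_fraction,
                  self.p_absent_nonresponder, self.p_absent_responder):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        lo, hi = self.n_clones
        if not 1 <= lo <= hi:
            raise ValueError("n_clones range must satisfy 1 <= lo <= hi")
        if hi > 4 ** self.germline_length:
            raise ValueError("more clones requested than distinct sequences exist")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError("marker genes exceed the total gene count")


@dataclass
class SimTruth:
    """Ground truth aligned one-to-one with the emitted samples."""

    proportions: dict[str, np.ndarray] = field(default_factory=dict)
    sub_fraction: dict[str, float] = field(default_factory=dict)
    evenness: dict[str, float] = field(default_factory=dict)
    evenness_z: dict[str, float] = field(default_factory=dict)
    response: dict[str, str] = field(default_factory=dict)
    ighg_absent: dict[str, bool] = field(default_factory=dict)
    class_labels: dict[str, str] = field(default_factory=dict)
    beta_evenness: float = 0.0
    shm_rate: float = 0.0
    dirichlet_alpha: float = 0.0


_GERMLINE_SEED = 20190528  # fixed: the bundled reference never varies


def bundled_germline(n: int = 3, length: int = 300) -> GermlineReference:
    """The package's bundled synthetic germline V panel (deterministic)."""
    rng = np.random.default_rng(_GERMLINE_SEED)
    entries = {}
    for i in range(n):
        seq = rng.choice(_BASES, size=length)
        entries[f"IGHV-S{i + 1}"] = seq.tobytes().decode()
    return GermlineReference(entries=entries)


def _mutate(germ: np.ndarray, mu: float, indel_rate: float,
            rng: np.random.Generator) -> tuple[str, int]:
    """Apply i.i.d. substitutions (and optional indels) to a germline array.

    Returns (sequence, n_substitutions). Substituted bases always differ
    from the germline base, so n_substitutions / length is the exact
    divergence when indel_rate is 0.
    """
    seq = germ.copy()
    mask = rng.random(seq.size) < mu
    n_sub = int(mask.sum())
    if n_sub:
        # shift each masked base by 1-3 positions in the ACGT cycle
        idx = np.where(mask)[0]
        base_idx = np.searchsorted(_BASES, seq[idx])
        shift = rng.integers(1, 4, size=idx.size)
        seq[idx] = _BASES[(base_idx + shift) % 4]
    if indel_rate > 0:
        keep = rng.random(seq.size) >= indel_rate
        seq = seq[keep]
    return seq.tobytes().decode(), n_sub


def simulate_repertoire(cfg: SimConfig, rng: np.random.Generator,
                        sample_id: str = "S1", chain: str = "IGHG",
                        germline: GermlineReference | None = None
                        ) -> tuple[Repertoire, SimTruth]:
    """One repertoire: Dirichlet clone proportions, multinomial counts,
    germline-derived mutated sequences (unique; collisions resampled)."""
    if germline is None:
        germline = bundled_germline(cfg.n_germline, cfg.germline_length)
    n_clones = int(rng.integers(cfg.n_clones[0], cfg.n_clones[1] + 1))
    props = rng.dirichlet(np.full(n_clones, cfg.dirichlet_alpha))
    if cfg.total_reads_sdlog > 0:
        total = max(1, int(round(rng.lognormal(math.log(cfg.total_reads),
                                               cfg.total_reads_sdlog))))
    else:
        total = cfg.total_reads
    counts = rng.multinomial(total, props)
    genes = sorted(germline.entries)
    germ_arrays = {g: np.frombuffer(germline.entries[g].encode(), dtype="S1")
                   for g in genes}
    clones: dict[str, CloneRecord] = {}
    total_subs = 0
    total_bases = 0
    for i in range(n_clones):
        if counts[i] == 0:
            continue
        gene = genes[int(rng.integers(len(genes)))]
        retries = 10 if cfg.shm_rate > 0 else 1
        for _ in range(retries):
            seq, n_sub = _mutate(germ_arrays[gene], cfg.shm_rate,
                                 cfg.indel_rate, rng)
            if seq not in clones:
                break
        if seq in clones:
            # mutation cannot tell the clones apart (e.g. mu = 0): merge counts
            old = clones[seq]
            clones[seq] = CloneRecord(sample_id=sample_id, chain=chain,
                                      sequence=seq,
                                      count=old.count + int(counts[i]),
                                      v_call=old.v_call)
            continue
        total_subs += n_sub
        total_bases += germ_arrays[gene].size
        clones[seq] = CloneRecord(sample_id=sample_id, chain=chain,
                                  sequence=seq, count=int(counts[i]),
                                  v_call=gene)
    rep = Repertoire(sample_id=sample_id, chain=chain,
                     clones=list(clones.values()),
                     library_size=cfg.library_size)
    truth = SimTruth(beta_evenness=cfg.beta_evenness, shm_rate=cfg.shm_rate,
                     dirichlet_alpha=cfg.dirichlet_alpha)
    truth.proportions[sample_id] = props
    truth.sub_fraction[sample_id] = (total_subs / total_bases
                                     if total_bases else 0.0)
    return rep, truth


def _censoring_hazard(target: float, hazards: np.ndarray) -> float:
    """Censoring hazard c with mean P(censor) = E[c / (c + lambda_i)] equal
    to the target rate."""
    if target <= 0:
        return 0.0
    if target >= 1:
        warnings.warn("censoring target 1.0 is infeasible; using a very "
                      "heavy censoring hazard", stacklevel=2)
        return float(hazards.max() * 1e6)

    def gap(c: float) -> float:
        return float(np.mean(c / (c + hazards))) - target

    hi = float(hazards.max())
    while gap(hi) < 0:
        hi *= 10
        if hi > 1e12:
            warnings.warn("censoring target infeasible", stacklevel=2)
            return hi
    return float(brentq(gap, 1e-15, hi))


def simulate_cohort(cfg: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[list[Repertoire], list[ClinicalRecord], SimTruth]:
    """A full cohort: per-sample repertoires, survival linked to
    standardized evenness, response linked to IGHG presence.

    Survival: T_i ~ Exp(h0 * exp(beta * z_i)) with z_i the standardized
    species evenness (H/S) of the sample's IGHG repertoire; censoring is an
    independent exponential calibrated to the target censoring fraction.
    Samples flagged IGHG-absent by the response model have their IGHG
    repertoire removed from the output (their survival is still generated
    from the pre-removal evenness, so absence is non-informative).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    master = np.random.SeedSequence(rng.integers(2 ** 31))
    children = master.spawn(cfg.n_samples + 1)
    cohort_rng = np.random.default_rng(children[-1])
    germline = bundled_germline(cfg.n_germline, cfg.germline_length)

    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    truth = SimTruth(beta_evenness=cfg.beta_evenness, shm_rate=cfg.shm_rate,
                     dirichlet_alpha=cfg.dirichlet_alpha)
    repertoires: list[Repertoire] = []
    per_sample_reps: dict[str, list[Repertoire]] = {}
    evenness = np.empty(cfg.n_samples)
    for i, sid in enumerate(sample_ids):
        srng = np.random.default_rng(children[i])
        reps = []
        for chain in cfg.chains:
            rep, rt = simulate_repertoire(cfg, srng, sample_id=sid,
                                          chain=chain, germline=germline)
            reps.append(rep)
            if chain == "IGHG":
                truth.proportions[sid] = rt.proportions[sid]
                truth.sub_fraction[sid] = rt.sub_fraction[sid]
        per_sample_reps[sid] = reps
        ighg = next(r for r in reps if r.chain == "IGHG")
        p = diversity.clone_proportions(ighg)
        evenness[i] = diversity.species_evenness(p, "shannon_over_richness")
        truth.evenness[sid] = float(evenness[i])

    z = (evenness - evenness.mean()) / evenness.std(ddof=1)
    hazards = cfg.baseline_hazard * np.exp(cfg.beta_evenness * z)
    event_times = cohort_rng.exponential(1.0 / hazards)
    c_hazard = _censoring_hazard(cfg.censoring_rate, hazards)
    if c_hazard > 0:
        censor_times = cohort_rng.exponential(1.0 / c_hazard,
                                              size=cfg.n_samples)
    else:
        censor_times = np.full(cfg.n_samples, np.inf)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)

    is_responder = cohort_rng.random(cfg.n_samples) < cfg.responder_fraction
    p_absent = np.where(is_responder, cfg.p_absent_responder,
                        cfg.p_absent_nonresponder)
    absent = cohort_rng.random(cfg.n_samples) < p_absent

    sexes = np.where(cohort_rng.random(cfg.n_samples) < 0.6, "male", "female")
    stages = cohort_rng.choice(["I", "II", "III", "IV"], size=cfg.n_samples,
                               p=[0.2, 0.3, 0.3, 0.2])
    sites = cohort_rng.choice(["primary", "regional", "distant"],
                              size=cfg.n_samples, p=[0.25, 0.45, 0.30])
    ages = np.clip(cohort_rng.normal(58.0, 13.0, size=cfg.n_samples), 18, 95)

    clinical: list[ClinicalRecord] = []
    for i, sid in enumerate(sample_ids):
        truth.evenness_z[sid] = float(z[i])
        truth.response[sid] = "responder" if is_responder[i] else "non_responder"
        truth.ighg_absent[sid] = bool(absent[i])
        for rep in per_sample_reps[sid]:
            if rep.chain == "IGHG" and absent[i]:
                continue
            repertoires.append(rep)
        clinical.append(ClinicalRecord(
            sample_id=sid, os_time=float(os_time[i]), os_event=int(os_event[i]),
            age=float(round(ages[i], 1)), sex=str(sexes[i]),
            stage=str(stages[i]), tissue_site=str(sites[i]),
            response=truth.response[sid]))
    return repertoires, clinical, truth


def simulate_expression(cfg: SimConfig, rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Class-structured log2 expression: class k shifts its own marker
    block by ``effect_size`` over N(0, noise_sd) noise on a baseline of 8."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    classes = [f"class_{chr(ord('a') + k)}" for k in range(cfg.n_classes)]
    labels = pd.Series([classes[i % cfg.n_classes] for i in range(cfg.n_samples)],
                       index=samples, name="class")
    base = np.full((cfg.n_genes, cfg.n_samples), 8.0)
    for k in range(cfg.n_classes):
        rows = np.arange(k * cfg.markers_per_class, (k + 1) * cfg.markers_per_class)
        cols = np.where((labels == classes[k]).to_numpy())[0]
        base[np.ix_(rows, cols)] += cfg.effect_size
    values = base + rng.normal(0.0, cfg.noise_sd, size=base.shape)
    return pd.DataFrame(values, index=genes, columns=samples), labels
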