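"""Seeded generator of longitudinal clone tables with known ground truth.

The generator emulates the statistical structure the Clone-Attractor
method assumes, so that every downstream stage can be tested against a
known answer:

* attractor basin sizes follow a discrete power law ``P(K) ~ K^-alpha``
  (default exponent 3) truncated to a size range;
* each attractor has a seed CDR3 sequence on a ``CASS...F`` scaffold and
  ``K - 1`` distinct members within the association radius lambda of the
  seed (at most two indels, or one substitution plus at most one indel);
* a set of *hub* attractors (basin >= 10) whose seeds form short mutation
  chains, so that consecutive hubs lie within graph-edge distance of each
  other while remaining well separated (> lambda) for clustering;
* two groups of samples followed over time: hub activity in the control
  group decays geometrically (dilution), hubs in the transgenic group
  persist — the mechanism behind the dense-vs-branched divergence of the
  two groups' graphs;
* a pool of *ubiquitous* attractors active in essentially every data
  point (the classifier's feature space), a subset of which carries a
  multiplicative group signal (stage 1) or cancer signal (stage 2);
* transgenic phenotypes progress healthy -> pre_cancer -> cancer with a
  per-mouse onset time; the pre-cancer point is the last one before
  cancer.

Per-member abundances are log-normal when an attractor is active in a
(sample, time point), zero otherwise.  Everything is reproducible from a
single seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tcranet.clustering import ActivityMatrix, AttractorSet, CloneAttractor, attractor_activity
from tcranet.distance import TOL, EditWeights, weighted_levenshtein
from tcranet.errors import ConfigurationError
from tcranet.io import AA_ALPHABET, CloneRecord, SampleMeta, frame_to_records

logger = logging.getLogger(__name__)

# member mutation kinds and their sampling probabilities; every kind costs
# <= 3.0 under the default weights (1.1, 1.1, 1.9).  The mix leans towards
# substitutions and insertions: deletion variants sort before their seed in
# the length-ordered greedy pass and can found off-centre clusters, so a
# deletion-heavy ball would fragment under the exact algorithm under test.
_MUTATION_KINDS = (
    ("sub", 0.40),
    ("ins", 0.30),
    ("del", 0.10),
    ("sub+ins", 0.10),
    ("ins+ins", 0.05),
    ("del+ins", 0.05),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic benchmark.

    Sample counts and time points mirror the reference design (5 control
    and 10 transgenic mice over 8 monthly time points); attractor sizes
    follow a power law with exponent 3.
    """

    n_attractors: int = 400
    alpha: float = 3.0
    size_range: tuple[int, int] = (1, 1000)
    member_edit_budget: float = 3.0
    n_control: int = 5
    n_transgenic: int = 10
    n_timepoints: int = 8
    amplitude_mu: float = 1.0      # log-normal location of member counts
    amplitude_sigma: float = 1.0   # log-normal scale of member counts
    p_active_background: float = 0.3
    dilution_rate: float = 0.7     # per-time-step hub activity decay, control group
    persistence: float = 0.95      # hub activity probability, transgenic group
    n_hubs: int = 25
    hub_chain_length: int = 5
    n_ubiquitous: int = 24
    p_active_ubiquitous: float = 0.99
    n_signal_cas_stage1: int = 3
    n_signal_cas_stage2: int = 3
    effect_size: float = 4.0           # group signal, multiplicative, > 1
    effect_size_stage2: float = 3.0    # cancer signal, weaker than stage 1
    onset_range: tuple[int, int] = (5, 8)  # first cancer time point, per mouse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_attractors <= 0 or self.n_timepoints <= 0:
            raise ConfigurationError("counts must be positive")
        if self.alpha <= 1:
            raise ConfigurationError("alpha must exceed 1")
        lo, hi = self.size_range
        if not (1 <= lo <= hi):
            raise ConfigurationError(f"infeasible size_range {self.size_range}")
        if self.n_hubs > 0 and hi < 10:
            raise ConfigurationError("hub attractors need size_range[1] >= 10")
        if self.n_ubiquitous < self.n_signal_cas_stage1 + self.n_signal_cas_stage2:
            raise ConfigurationError("not enough ubiquitous attractors to plant signals")
        if self.effect_size < 1 or self.effect_size_stage2 < 1:
            raise ConfigurationError("effect sizes must be >= 1")
        if not 1 <= self.onset_range[0] <= self.onset_range[1] <= self.n_timepoints:
            raise ConfigurationError("onset_range must lie within the time points")


@dataclass
class GroundTruth:
    """Generator-side truth aligned with the emitted clone table."""

    seed_by_ca: dict[int, str]
    member_to_ca: dict[str, int]
    sizes: dict[int, int]
    hub_ids: list[int]
    ubiquitous_ids: list[int]
    signal_stage1: list[int]
    signal_stage2: list[int]
    group_by_sample: dict[str, str]
    phenotype: dict[tuple[str, int], str]  # (sample_id, time_point) -> phenotype

    def to_attractor_set(self, weights: EditWeights = EditWeights()) -> AttractorSet:
        """The true clustering, as an :class:`AttractorSet` (seed = representative)."""
        members_by_ca: dict[int, dict[str, int]] = {ca: {} for ca in self.seed_by_ca}
        for seq, ca in self.member_to_ca.items():
            members_by_ca[ca][seq] = 1
        attractors = [
            CloneAttractor(ca, self.seed_by_ca[ca], members)
            for ca, members in sorted(members_by_ca.items())
        ]
        return AttractorSet(attractors, weights)


@dataclass
class SimResult:
    """Clone table + metadata + ground truth of one generated experiment."""

    clones: pd.DataFrame       # junction_aa, duplicate_count, sample_id, time_point
    metadata: pd.DataFrame     # sample_id, time_point, group, phenotype
    truth: GroundTruth
    config: SimConfig

    def clone_records(self) -> list[CloneRecord]:
        return frame_to_records(self.clones)

    def sample_metas(self) -> list[SampleMeta]:
        metas = []
        for sample_id, sub in self.metadata.groupby("sample_id", sort=True):
            metas.append(
                SampleMeta(
                    sample_id,
                    sub["group"].iloc[0],
                    {int(r.time_point): r.phenotype for r in sub.itertuples(index=False)},
                )
            )
        return metas

    def truth_activity(self, weights: EditWeights = EditWeights()) -> tuple[AttractorSet, ActivityMatrix]:
        """Activity matrix computed from the *true* membership (no clustering)."""
        aset = self.truth.to_attractor_set(weights)
        return aset, attractor_activity(aset, self.clone_records())


def _power_law_sizes(rng, n, alpha, lo, hi):
    k = np.arange(lo, hi + 1, dtype=float)
    p = k ** -alpha
    p /= p.sum()
    return rng.choice(k.astype(int), size=n, p=p)


def _random_scaffold_seq(rng, length: int) -> str:
    middle = "".join(rng.choice(list(AA_ALPHABET), size=length - 5))
    return "CASS" + middle + "F"


def _substitute(rng, seq: str, pos: int) -> str:
    choices = [c for c in AA_ALPHABET if c != seq[pos]]
    return seq[:pos] + rng.choice(choices) + seq[pos + 1 :]


def _mutate_once(rng, seq: str, op: str) -> str:
    if op == "sub":
        return _substitute(rng, seq, int(rng.integers(len(seq))))
    if op == "del":
        pos = int(rng.integers(len(seq)))
        return seq[:pos] + seq[pos + 1 :]
    pos = int(rng.integers(len(seq) + 1))  # insertion
    return seq[:pos] + rng.choice(list(AA_ALPHABET)) + seq[pos:]


def _draw_member(rng, seed_seq: str) -> str:
    kinds, probs = zip(*_MUTATION_KINDS)
    kind = kinds[rng.choice(len(kinds), p=probs)]
    out = seed_seq
    for op in kind.split("+"):
        if op == "del" and len(out) <= 8:
            op = "ins"  # keep sequences CDR3-sized
        out = _mutate_once(rng, out, op)
    return out


def _hub_chain_seeds(rng, n_hubs: int, chain_length: int) -> list[list[str]]:
    """Seeds of hub attractors arranged in mutation chains.

    Chain neighbours share all but <= 4 positions (representative distance
    <= 4 substitutions = 7.6, i.e. within the default graph-edge cutoff of
    8) while any two chain members differ by >= 2 substitutions (3.8 > 3,
    safely outside the clustering radius).
    """
    chains: list[list[str]] = []
    remaining = n_hubs
    while remaining > 0:
        this_len = min(chain_length, remaining)
        base = _random_scaffold_seq(rng, 16)  # 11 middle positions
        chain = []
        for k in range(this_len):
            seq = base
            for pos in (4 + k, 4 + k + 1, 4 + k + 2):  # window in the middle segment
                seq = _substitute(rng, seq, pos)
            chain.append(seq)
        chains.append(chain)
        remaining -= this_len
    return chains


def generate(cfg: SimConfig) -> SimResult:
    """Generate one longitudinal experiment; reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.size_range
    weights = EditWeights()

    # ---- attractor categories and sizes ---------------------------------
    regular_ids = list(range(cfg.n_attractors))
    sizes = dict(zip(regular_ids, _power_law_sizes(rng, cfg.n_attractors, cfg.alpha, lo, hi)))
    next_id = cfg.n_attractors
    hub_ids = list(range(next_id, next_id + cfg.n_hubs))
    if cfg.n_hubs:
        hub_sizes = _power_law_sizes(rng, cfg.n_hubs, cfg.alpha, 10, max(hi, 10))
        sizes.update(zip(hub_ids, hub_sizes))
    next_id += cfg.n_hubs
    ubiq_ids = list(range(next_id, next_id + cfg.n_ubiquitous))
    if cfg.n_ubiquitous:
        ubiq_sizes = _power_law_sizes(rng, cfg.n_ubiquitous, cfg.alpha, 3, max(min(hi, 9), 3))
        sizes.update(zip(ubiq_ids, ubiq_sizes))
    sizes = {ca: int(k) for ca, k in sizes.items()}

    # ---- seed sequences --------------------------------------------------
    taken: set[str] = set()
    seed_by_ca: dict[int, str] = {}

    def _claim(seq: str) -> bool:
        if seq in taken:
            return False
        taken.add(seq)
        return True

    hub_seed_list = [s for chain in _hub_chain_seeds(rng, cfg.n_hubs, cfg.hub_chain_length) for s in chain]
    for ca, seq in zip(hub_ids, hub_seed_list):
        if not _claim(seq):
            raise ConfigurationError("hub seed collision; choose another seed")
        seed_by_ca[ca] = seq
    for ca in regular_ids + ubiq_ids:
        for _ in range(1000):
            seq = _random_scaffold_seq(rng, int(rng.integers(10, 18)))
            if _claim(seq):
                seed_by_ca[ca] = seq
                break
        else:
            raise ConfigurationError("could not draw a unique seed sequence")

    # ---- members within the lambda ball ---------------------------------
    member_to_ca: dict[str, int] = {}
    members_by_ca: dict[int, list[str]] = {}
    budget = cfg.member_edit_budget + TOL
    for ca in sorted(sizes):
        seed_seq = seed_by_ca[ca]
        members = [seed_seq]
        member_to_ca[seed_seq] = ca
        misses = 0
        while len(members) < sizes[ca]:
            cand = _draw_member(rng, seed_seq)
            if cand in taken or weighted_levenshtein(seed_seq, cand, weights) > budget:
                misses += 1
                if misses > 200 + 50 * sizes[ca]:
                    raise ConfigurationError(
                        f"size_range infeasible: cannot draw {sizes[ca]} distinct members "
                        f"within edit budget {cfg.member_edit_budget} of {seed_seq!r}"
                    )
                continue
            taken.add(cand)
            members.append(cand)
            member_to_ca[cand] = ca
        members_by_ca[ca] = members

    # ---- samples, phenotypes --------------------------------------------
    samples = [f"C{i + 1:02d}" for i in range(cfg.n_control)] + [
        f"T{i + 1:02d}" for i in range(cfg.n_transgenic)
    ]
    group_by_sample = {
        s: ("control" if s.startswith("C") else "transgenic") for s in samples
    }
    tps = list(range(1, cfg.n_timepoints + 1))
    phenotype: dict[tuple[str, int], str] = {}
    for s in samples:
        if group_by_sample[s] == "control":
            for t in tps:
                phenotype[(s, t)] = "healthy"
        else:
            onset = int(rng.integers(cfg.onset_range[0], cfg.onset_range[1] + 1))
            for t in tps:
                if t >= onset:
                    phenotype[(s, t)] = "cancer"
                elif t == onset - 1:
                    phenotype[(s, t)] = "pre_cancer"
                else:
                    phenotype[(s, t)] = "healthy"

    signal_pool = list(rng.permutation(ubiq_ids)) if ubiq_ids else []
    signal_stage1 = [int(x) for x in signal_pool[: cfg.n_signal_cas_stage1]]
    signal_stage2 = [
        int(x)
        for x in signal_pool[cfg.n_signal_cas_stage1 : cfg.n_signal_cas_stage1 + cfg.n_signal_cas_stage2]
    ]

    # ---- activity and amplitudes ----------------------------------------
    hub_set, ubiq_set = set(hub_ids), set(ubiq_ids)
    s1_set, s2_set = set(signal_stage1), set(signal_stage2)
    rows_seq: list[str] = []
    rows_count: list[int] = []
    rows_sample: list[str] = []
    rows_tp: list[int] = []
    for ca in sorted(sizes):
        members = members_by_ca[ca]
        k = len(members)
        for s in samples:
            transgenic = group_by_sample[s] == "transgenic"
            for t in tps:
                if ca in hub_set:
                    p = cfg.persistence if transgenic else cfg.persistence * cfg.dilution_rate ** (t - 1)
                elif ca in ubiq_set:
                    p = cfg.p_active_ubiquitous
                else:
                    p = cfg.p_active_background
                if rng.random() >= p:
                    continue
                factor = 1.0
                if ca in s1_set and transgenic:
                    factor *= cfg.effect_size
                if ca in s2_set and phenotype[(s, t)] == "cancer":
                    factor *= cfg.effect_size_stage2
                counts = rng.lognormal(cfg.amplitude_mu, cfg.amplitude_sigma, size=k) * factor
                counts = np.maximum(1, np.rint(counts)).astype(int)
                rows_seq.extend(members)
                rows_count.extend(counts.tolist())
                rows_sample.extend([s] * k)
                rows_tp.extend([t] * k)

    clones = pd.DataFrame(
        {
            "junction_aa": rows_seq,
            "duplicate_count": rows_count,
            "sample_id": rows_sample,
            "time_point": rows_tp,
        }
    )
    metadata = pd.DataFrame(
        [(s, t, group_by_sample[s], phenotype[(s, t)]) for s in samples for t in tps],
        columns=["sample_id", "time_point", "group", "phenotype"],
    )
    truth = GroundTruth(
        seed_by_ca=seed_by_ca,
        member_to_ca=member_to_ca,
        sizes=sizes,
        hub_ids=hub_ids,
        ubiquitous_ids=ubiq_ids,
        signal_stage1=signal_stage1,
        signal_stage2=signal_stage2,
        group_by_sample=group_by_sample,
        phenotype=phenotype,
    )
    logger.info(
        "generated %d attractors (%d hubs, %d ubiquitous), %d sequences, %d clone rows",
        len(sizes), len(hub_ids), len(ubiq_ids), len(member_to_ca), len(clones),
    )
    return SimResult(clones, metadata, truth, cfg)


def benchmark_suite(seed: int = 0, cfg: SimConfig | None = None) -> dict[str, SimResult]:
    """The standard benchmark bundle: the default variant plus a ``null``
    variant with unit effect sizes (no planted class signal) for
    false-positive checks."""
    base = cfg if cfg is not None else SimConfig(seed=seed)
    if base.seed != seed:
        base = dataclasses.replace(base, seed=seed)
    null_cfg = dataclasses.replace(base, effect_size=1.0, effect_size_stage2=1.0)
    return {"default": generate(base), "null": generate(null_cfg)}
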