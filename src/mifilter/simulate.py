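"""Seeded mock-community simulation with known true/contaminant labels.

The generator emulates the structure of a sequenced mock community: a small
set of genuinely present, strongly associated, high-abundance taxa plus many
sparse, low-abundance contaminant taxa, with counts drawn multinomially at a
fixed sequencing depth (compositional closure included).

Design.  Mock communities are built from *prescribed mixtures*: each sample
realises one of ``n_states`` community states, and every true taxon carries a
prescribed relative abundance level per state (a scaled permutation of
``0..n_states-1``, level 0 meaning absent from that mixture).  Taxon
abundances therefore vary over well-separated linear levels — the feature
that makes histogram-discretized mutual information between true taxa high,
as in real mixture designs.  Structure is controlled by ``rho``:

* "leader" taxa follow the sample's community state with probability
  ``rho`` (graded slightly across leaders), otherwise drawing an
  idiosyncratic state;
* each remaining true taxon tracks a designated leader (prescribed
  co-proportions, as for strains mixed together) with probability
  ``rho**(1/3)``, giving every true taxon one strong network partner.

At ``rho = 0`` every true taxon draws its state independently and all
association vanishes.

Contaminants are independent level-permutation taxa scaled down by
``10**(-abundance_gap)`` relative to the true community, so at
``abundance_gap = 0`` and ``sparsity = 1`` they are statistically
exchangeable with uncoupled true taxa.  Their per-sample presence is
batch-structured (reagent/cross-contamination style): each contaminant
belongs to one of ``n_batches`` sample batches and appears more often
within it.  This reproduces the weak contaminant co-occurrence real tables
show at low network thresholds while keeping contaminants independent of
the true community.

The default preset mirrors the published vaginal mock community this method
was validated on: 240 samples, 7 true strains, 39 contaminant ASVs, depth
15000 (≈ 3.67M reads / 240 samples) and a 4-log10 abundance gap (most
frequent contaminant ≈ 10⁻⁴ relative abundance).

All randomness flows from the spec's single seed through a fixed draw
order, so identical specs reproduce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .table import CountTable

__all__ = [
    "CommunitySpec",
    "generate_community",
    "generate_null_table",
    "brooks_like_spec",
]

_TRUE_STRAINS = (
    "Atopobium_vaginae",
    "Gardnerella_vaginalis",
    "Lactobacillus_crispatus",
    "Lactobacillus_iners",
    "Prevotella_bivia",
    "Sneathia_amnii",
    "Streptococcus_agalactiae",
)


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one simulated mock community."""

    n_samples: int = 240
    n_true_taxa: int = 7
    n_contaminants: int = 39
    rho: float = 0.9                  # association level among true taxa
    abundance_gap: float = 4.0        # log10 gap true community → contaminant
    sparsity: float = 0.2             # mean per-sample presence prob. of contaminants
    depth: int = 15000                # reads per sample
    n_states: int = 8                 # number of prescribed community states
    level_noise: float = 0.02         # log-scale noise on leader abundances
    partner_noise: float = 0.05       # log-scale noise on follower/contaminant abundances
    n_batches: int = 4                # contamination batches
    batch_boost: float = 3.0          # in-batch presence multiplier
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_true_taxa < 1 or self.n_contaminants < 0:
            raise ValueError("community dimensions are infeasible")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if not 0.0 <= self.sparsity <= 1.0:
            raise ValueError("sparsity must lie in [0, 1]")
        if self.depth < 1:
            raise ValueError("sequencing depth must be positive")
        if self.n_states < 2 or self.n_batches < 1:
            raise ValueError("need at least 2 states and 1 batch")


def brooks_like_spec(seed: int = 0, **overrides) -> CommunitySpec:
    """The default strong-signal mock-community preset (see module docstring)."""
    return replace(CommunitySpec(seed=seed), **overrides)


def _leader_of(j: int, n_true: int) -> int | None:
    """Partner topology: even taxa lead, odd taxa follow their predecessor;
    with an odd taxon count the last taxon joins the previous pair as a trio."""
    if j % 2 == 1:
        return j - 1
    if n_true % 2 == 1 and j == n_true - 1 and n_true >= 3:
        return n_true - 3
    return None


def _taxon_ids(spec: CommunitySpec) -> tuple[list[str], list[str]]:
    if spec.n_true_taxa <= len(_TRUE_STRAINS):
        true_ids = list(_TRUE_STRAINS[: spec.n_true_taxa])
    else:
        true_ids = [f"TRUE_{j + 1:03d}" for j in range(spec.n_true_taxa)]
    contam_ids = [f"CON_{j + 1:03d}" for j in range(spec.n_contaminants)]
    return true_ids, contam_ids


def generate_community(spec: CommunitySpec) -> tuple[CountTable, pd.Series]:
    """Simulate one labelled count table.

    Returns the samples × taxa table and a taxon-indexed label Series with
    values ``"true"`` / ``"contaminant"``.
    """
    rng = np.random.default_rng(spec.seed)
    n, t, c, k = spec.n_samples, spec.n_true_taxa, spec.n_contaminants, spec.n_states

    leaders = [j for j in range(t) if _leader_of(j, t) is None]
    perms = {j: rng.permutation(k) for j in leaders}
    level_of = {
        j: perms[j if _leader_of(j, t) is None else _leader_of(j, t)]
        for j in range(t)
    }
    offsets = np.exp(np.linspace(-0.5, 0.5, t)) if t > 1 else np.ones(1)
    w_levels = np.column_stack([level_of[j] for j in range(t)]).astype(float)
    w_levels *= offsets[None, :]
    max_total = w_levels.sum(axis=1).max() * 1.05  # headroom absorbed by filler reads

    states = rng.integers(0, k, n)
    rho_leader = spec.rho * np.linspace(0.88, 1.06, len(leaders))
    lead_state: dict[int, np.ndarray] = {}
    for i, j in enumerate(leaders):
        follows = rng.random(n) < min(rho_leader[i], 0.99)
        idio = rng.integers(0, k, n)
        lead_state[j] = np.where(follows, states, idio)
    p_pair = min(spec.rho ** (1.0 / 3.0), 0.99)

    chosen = np.empty((n, t), dtype=np.int64)
    for j in range(t):
        lead = _leader_of(j, t)
        if lead is None:
            chosen[:, j] = lead_state[j]
        else:
            tracks = rng.random(n) < p_pair
            chosen[:, j] = np.where(tracks, lead_state[lead], rng.integers(0, k, n))
    is_leader = np.array([_leader_of(j, t) is None for j in range(t)])
    log_noise = np.where(is_leader[None, :], spec.level_noise, spec.partner_noise)
    w_true = w_levels[chosen, np.arange(t)[None, :]] * np.exp(
        log_noise * rng.standard_normal((n, t))
    )
    w_true /= max_total
    filler = np.clip(1.0 - w_true.sum(axis=1, keepdims=True), 0.0, None)

    # contaminants: independent level taxa with batch-structured presence
    batches = rng.integers(0, spec.n_batches, n)
    con_batch = rng.integers(0, spec.n_batches, c)
    con_perms = (
        np.column_stack([rng.permutation(k) for _ in range(c)]).astype(float)
        if c
        else np.zeros((k, 0))
    )
    con_states = rng.integers(0, k, (n, c))
    con_offsets = np.exp(rng.normal(0.0, 0.3, c))
    p_in = min(spec.batch_boost * spec.sparsity, 1.0)
    p_out = spec.sparsity * (0.25 + 0.75 * spec.sparsity ** 2)
    p_present = np.where(batches[:, None] == con_batch[None, :], p_in, p_out)
    present = rng.random((n, c)) < p_present
    con_noise = spec.partner_noise * rng.standard_normal((n, c))
    w_con = (
        present
        * 10.0 ** (-spec.abundance_gap)
        * con_perms[con_states, np.arange(c)[None, :]]
        * con_offsets[None, :]
        * np.exp(con_noise)
        / max_total
    )

    weights = np.concatenate([w_true, w_con, filler], axis=1)
    weights = np.clip(weights, 0.0, None)
    weights /= weights.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(spec.depth, weights[i]) for i in range(n)]
    )[:, : t + c]

    true_ids, contam_ids = _taxon_ids(spec)
    taxon_ids = true_ids + contam_ids
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    table = CountTable(counts, tuple(sample_ids), tuple(taxon_ids))
    labels = pd.Series(
        ["true"] * t + ["contaminant"] * c, index=taxon_ids, name="label"
    )
    return table, labels


def generate_null_table(
    n: int,
    m: int,
    seed: int | None = None,
    mean: float = 20.0,
    dispersion: float = 2.0,
) -> CountTable:
    """i.i.d.-taxon table with no dependence structure.

    Every cell is an independent negative-binomial draw (size ``dispersion``,
    mean ``mean``), so all taxa are exchangeable — the null model for
    type-I-error checks of the step tests.
    """
    if n < 2 or m < 2:
        raise ValueError("need at least 2 samples and 2 taxa")
    rng = np.random.default_rng(seed)
    p = dispersion / (dispersion + mean)
    counts = rng.negative_binomial(dispersion, p, size=(n, m))
    return CountTable(
        counts,
        tuple(f"S{i + 1:04d}" for i in range(n)),
        tuple(f"TAXON_{j + 1:03d}" for j in range(m)),
    )
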