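"""Synthetic genomes and variants with known ground truth.

Genomes are sampled left-to-right from an explicit conditional table
(i.i.d. or Markov of a given order), variants from an explicit alpha matrix
combined with a genome model, so every estimator in the package has a
recovery test that needs no external data. All sampling is reproducible
from (spec, seed) alone; the generator never emits N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kmers import BASES, kmer_to_int, encode
from .context_models import InterpolatedContextModel
from .sequence_io import Genome, VariantRecord
from .substitution_model import AlphaMatrix, mutability_track

__all__ = ["GeneratorSpec", "sample_genome", "sample_variants",
           "make_toy_fixture", "ToyFixture", "uniform_iid_spec"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Explicit sequence distribution to sample from.

    conditional_table has shape (4**order, 4): row s is the distribution of
    the next base given the packed order-mer context s. kind "iid" is the
    order=0 special case. The first `order` bases of a Markov sequence are
    drawn i.i.d. uniform (a negligible edge at the lengths used here).
    """

    kind: str
    order: int
    conditional_table: np.ndarray
    length: int
    seed: int
    initial: str | None = None   # fixed first `order` bases; default i.i.d. uniform

    def __post_init__(self):
        if self.initial is not None and len(self.initial) != self.order:
            raise ValueError("initial context must have `order` bases")
        if self.kind not in ("iid", "markov"):
            raise ValueError(f"unknown generator kind: {self.kind}")
        order = 0 if self.kind == "iid" else self.order
        table = np.asarray(self.conditional_table, float)
        if table.shape != (4 ** order, 4):
            raise ValueError(f"conditional table must be ({4 ** order}, 4)")
        if np.any(np.abs(table.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("conditional distributions must sum to 1")
        object.__setattr__(self, "conditional_table", table)


def uniform_iid_spec(length: int, seed: int) -> GeneratorSpec:
    return GeneratorSpec("iid", 0, np.full((1, 4), 0.25), length, seed)


def sample_genome(spec: GeneratorSpec, name: str = "chr1") -> Genome:
    """Sample one record of the requested length; seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    table = spec.conditional_table
    order = 0 if spec.kind == "iid" else spec.order
    if order == 0:
        seq = rng.choice(4, size=spec.length, p=table[0]).astype(np.uint8)
        return Genome([(name, seq)])
    n = spec.length
    seq = np.empty(n, np.uint8)
    head = min(order, n)
    if spec.initial is not None:
        seq[:head] = encode(spec.initial)[:head]
    else:
        seq[:head] = rng.integers(0, 4, size=head)
    if n <= order:
        return Genome([(name, seq)])
    cdf = np.cumsum(table, axis=1)
    u = rng.random(n)
    mask = 4 ** order
    state = 0
    for i in range(head):
        state = (state * 4 + int(seq[i])) % mask
    for i in range(order, n):
        row = cdf[state]
        ui = u[i]
        b = int(ui > row[0]) + int(ui > row[1]) + int(ui > row[2])
        seq[i] = b
        state = (state * 4 + b) % mask
    return Genome([(name, seq)])


def sample_variants(genome: Genome, alpha: AlphaMatrix,
                    genome_model: InterpolatedContextModel, seed: int,
                    leave_one_out: bool = False) -> list[VariantRecord]:
    """Draw at most one substitution per scored site.

    At each site the event {no change} + {three alts} is drawn once with
    probabilities {1 - sum mu, mu_ab}; the continuous-time model is
    collapsed to a single generation (time set to 1). Raises when any
    site's mu sum exceeds 1 (alpha too large for the first-order regime).
    """
    rng = np.random.default_rng(seed)
    track = mutability_track(alpha, genome_model, genome, leave_one_out)
    mu = track[[f"mu{b}" for b in BASES]].to_numpy()
    cum = np.cumsum(mu, axis=1)
    if np.any(cum[:, -1] > 1.0 + 1e-12):
        raise ValueError("per-site mutability sums exceed 1; "
                         "alpha outside the first-order regime")
    u = rng.random(len(track))
    alt_idx = (u[:, None] >= cum).sum(axis=1)  # 4 = no event
    hit = alt_idx < 4
    out = []
    chroms = track["chrom"].to_numpy()
    poss = track["pos"].to_numpy()
    refs = track["ref"].to_numpy()
    for i in np.flatnonzero(hit):
        alt = BASES[alt_idx[i]]
        if alt == refs[i]:  # mu toward ref is 0; cannot happen unless u==cum
            continue
        out.append(VariantRecord(str(chroms[i]), int(poss[i]),
                                 str(refs[i]), alt))
    return out


@dataclass
class ToyFixture:
    """Tiny hand-enumerated genomes and their expected count/probability values."""

    genome: Genome
    # strand-symmetrized central k=1 expectations for record "pal8"
    expected: dict = field(default_factory=dict)


def make_toy_fixture() -> ToyFixture:
    """Canonical desk-checkable fixtures shared by the test-suite.

    Record "pal8" = ACGTACGT equals its own reverse complement, so both
    strands contribute identical window sets. Hand enumeration of central
    k=1 windows (x, left, right) over both strands gives, for context A_G:
    forward windows at pos 1 and 5 (ACG), reverse-strand readings at pos 2
    and 6, hence n(C|A_G) = 4 = N(A_G). Leave-one-out at pos 1 removes the
    site's own reading, giving P(C) = 1. Record "mix5" = ACGTA carries the
    boundary and N-free-window conventions; "amb" holds an N.
    """
    genome = Genome([
        ("pal8", "ACGTACGT"),
        ("mix5", "ACGTA"),
        ("amb", "ACNTA"),
    ])
    expected = {
        # (record, context, base) -> strand-symmetrized count, central k=1
        ("pal8", "AG", "C"): 4,
        ("pal8", "AG", "N_total"): 4,
        # leave-one-out distribution at pal8 pos 1 (base C, context A_G)
        ("pal8", 1, "loo_P"): {"A": 0.0, "C": 1.0, "G": 0.0, "T": 0.0},
        # mix5 central contexts: pos 2 has flanks (AC, TA)
        ("mix5", 2, "context"): ("AC", "TA"),
        # amb pos 3 context contains N -> undefined
        ("amb", 3, "context"): None,
    }
    return ToyFixture(genome, expected)
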