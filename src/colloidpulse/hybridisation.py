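"""Competing DNA/RNA hybridisation equilibria of the linker system.

The 38-nt RNA linker can hybridise with (i) a fully complementary 38-nt RNA
added as an "aggregation threshold" (the RNA/RNA duplex is RNaseH-resistant),
(ii) the two 14-nt docking strands on the colloids (each overlapping one half
of the linker), and (iii) nothing else.  Degradation by-products — the two
half-linker fragments left when RNaseH cleaves the colloid-bound part — can
re-occupy docking strands and block bridging ("history" effect).

All binding is bimolecular mass action, [AB] = K * [A]free * [B]free, with
per-species conservation.  Such systems have a unique non-negative
equilibrium, solved here by a damped fixed-point iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from Bio import SeqIO

from .kinetics import RnaTrajectory

__all__ = [
    "SequenceFixture",
    "DuplexSpec",
    "HybridPool",
    "EquilibriumPartition",
    "EquilibriumError",
    "load_sequences",
    "overlap_length",
    "association_constant",
    "default_duplexes",
    "equilibrate",
    "effective_linker",
    "threshold_transform",
    "blocking_factor",
]

_IUPAC = set("ACGTUWSMKRYBDHVN")
_COMPLEMENT = str.maketrans("ACGTU", "TGCAA")

#: default two-parameter affinity rule K(overlap) = K0 * exp(gamma * overlap),
#: chosen so a 38-nt duplex binds essentially irreversibly at nM totals while
#: 14-nt duplexes have a Kd of a few tens of nM.  Illustrative, configurable.
DEFAULT_K0 = 1e-6  # nM^-1
DEFAULT_GAMMA = 0.7  # per nt


class EquilibriumError(RuntimeError):
    """Raised when the fixed-point solver does not converge; carries the residual."""


@dataclass(frozen=True)
class SequenceFixture:
    """A named oligonucleotide of the system (DNA or RNA)."""

    name: str
    sequence: str
    material: str  # "DNA" | "RNA"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in {self.name}: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class DuplexSpec:
    """An allowed duplex between two pool species with association constant K (nM^-1)."""

    species_a: str
    species_b: str
    K: float
    overlap: int = 1

    def __post_init__(self) -> None:
        if self.K < 0 or not np.isfinite(self.K):
            raise ValueError("K must be finite and >= 0")
        if self.overlap < 1:
            raise ValueError("overlap must be >= 1")
        if self.species_a == self.species_b:
            raise ValueError("self-duplexes are not modelled")


@dataclass(frozen=True)
class HybridPool:
    """Total concentrations (nM) of the competing species."""

    linker: float = 0.0
    complement: float = 0.0
    docking_a: float = 0.0
    docking_b: float = 0.0
    fragment_a: float = 0.0
    fragment_b: float = 0.0

    def __post_init__(self) -> None:
        for name, v in self.totals().items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"total {name} must be finite and >= 0, got {v!r}")

    def totals(self) -> Dict[str, float]:
        return {
            "linker": self.linker,
            "complement": self.complement,
            "docking_a": self.docking_a,
            "docking_b": self.docking_b,
            "fragment_a": self.fragment_a,
            "fragment_b": self.fragment_b,
        }


@dataclass(frozen=True)
class EquilibriumPartition:
    """Free concentrations per species and concentration per allowed duplex (nM)."""

    free: Dict[str, float]
    duplex: Dict[Tuple[str, str], float]
    residual: float  # worst per-species relative conservation error


def load_sequences() -> Dict[str, SequenceFixture]:
    """Load the packaged oligo fixtures (docking strands, template, linker, complement)."""
    out: Dict[str, SequenceFixture] = {}
    with resources.files("colloidpulse.data").joinpath("sequences.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            material = "DNA"
            for tok in rec.description.split():
                if tok.startswith("material="):
                    material = tok.split("=", 1)[1]
            out[rec.id] = SequenceFixture(rec.id, str(rec.seq), material)
    return out


def _normalise(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise ValueError(f"non-IUPAC characters: {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return _normalise(seq).translate(_COMPLEMENT)[::-1]


def overlap_length(a: SequenceFixture, b: SequenceFixture) -> int:
    """Length of the longest contiguous antiparallel Watson-Crick match.

    RNA U pairs like T; ambiguity codes are not expanded (only exact A-T/U and
    G-C matches count).  Computed as the longest common substring of ``a`` and
    the reverse complement of ``b`` by dynamic programming.
    """
    s = _normalise(a.sequence)
    t = reverse_complement(b.sequence)
    if not s or not t:
        raise ValueError("sequences must be non-empty")
    best = 0
    prev = [0] * (len(t) + 1)
    for ch in s:
        cur = [0] * (len(t) + 1)
        for j, ct in enumerate(t, start=1):
            if ch == ct:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def association_constant(
    overlap: int, k0: float = DEFAULT_K0, gamma: float = DEFAULT_GAMMA
) -> float:
    """Affinity rule K(overlap) = K0 * exp(gamma * overlap), in nM^-1."""
    return k0 * math.exp(gamma * overlap)


def default_duplexes(
    k0: float = DEFAULT_K0, gamma: float = DEFAULT_GAMMA
) -> List[DuplexSpec]:
    """The standard duplex set of the system with overlap-derived affinities.

    Overlaps are computed from the packaged sequences: the linker pairs fully
    (38 nt) with the added complementary RNA and half-length (14 nt) with each
    docking strand; each degradation fragment re-binds only its own docking
    strand (14 nt).
    """
    seqs = load_sequences()
    ov_ac = overlap_length(seqs["linker"], seqs["complement_rna"])
    ov_da = overlap_length(seqs["linker"], seqs["docking_A"])
    ov_db = overlap_length(seqs["linker"], seqs["docking_B"])
    mk = lambda a, b, ov: DuplexSpec(a, b, association_constant(ov, k0, gamma), ov)
    return [
        mk("linker", "complement", ov_ac),
        mk("linker", "docking_a", ov_da),
        mk("linker", "docking_b", ov_db),
        mk("fragment_a", "docking_a", ov_da),
        mk("fragment_b", "docking_b", ov_db),
    ]


def equilibrate(
    pool: HybridPool,
    duplexes: Iterable[DuplexSpec],
    tol: float = 1e-12,
    max_iter: int = 100_000,
) -> EquilibriumPartition:
    """Solve the coupled bimolecular mass-action equilibrium.

    Iterates x_i <- T_i / (1 + sum_j K_ij x_j) with geometric (square-root)
    damping, which is robust up to the strong-binding limit.  The bimolecular
    system's equilibrium is unique, so any convergent scheme finds it.
    Convergence: successive free concentrations within ``tol`` nM (absolute).
    """
    totals = pool.totals()
    names = list(totals)
    idx = {n: i for i, n in enumerate(names)}
    n = len(names)
    K = np.zeros((n, n))
    pairs: List[Tuple[str, str, float]] = []
    for d in duplexes:
        for sp in (d.species_a, d.species_b):
            if sp not in idx:
                raise ValueError(f"unknown species {sp!r}")
        i, j = idx[d.species_a], idx[d.species_b]
        K[i, j] += d.K
        K[j, i] += d.K
        pairs.append((d.species_a, d.species_b, d.K))

    T = np.array([totals[nm] for nm in names])
    x = T.copy()
    active = T > 0
    for _ in range(max_iter):
        denom = 1.0 + K @ x
        x_new = T / denom
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        # geometric damping; zero-total species stay at zero
        x = np.where(active, np.sqrt(np.maximum(x, 0.0) * x_new), 0.0)
    else:
        resid = float(np.max(np.abs(T - x * (1.0 + K @ x))))
        raise EquilibriumError(
            f"no convergence after {max_iter} iterations; "
            f"absolute conservation residual {resid:.3e} nM"
        )
    # one pure update tightens conservation: x*(1+Kx) == T by construction
    x = T / (1.0 + K @ x)

    free = {nm: float(x[idx[nm]]) for nm in names}
    duplex = {
        (a, b): float(k * x[idx[a]] * x[idx[b]]) for a, b, k in pairs
    }
    resid = 0.0
    for nm in names:
        if T[idx[nm]] > 0:
            bound = sum(c for (a, b), c in duplex.items() if nm in (a, b))
            resid = max(resid, abs(free[nm] + bound - totals[nm]) / totals[nm])
    return EquilibriumPartition(free=free, duplex=duplex, residual=resid)


def effective_linker(partition: EquilibriumPartition) -> float:
    """Free full-length linker (nM), the only species able to bridge both colloid types."""
    return partition.free["linker"]


def threshold_transform(
    traj: RnaTrajectory,
    complement_tot: float,
    duplexes: Optional[List[DuplexSpec]] = None,
) -> RnaTrajectory:
    """Map an RNA-linker pulse to the effective (free-linker) pulse.

    At each time point the hybridisation equilibrium with ``complement_tot``
    nM of complementary RNA is solved (quasi-static: hybridisation is fast
    relative to the enzymatic rates) and the free linker substituted.  With no
    complement the transform is the identity; output never exceeds input.
    """
    if complement_tot < 0:
        raise ValueError("complement_tot must be >= 0")
    if duplexes is None:
        seqs = load_sequences()
        ov = overlap_length(seqs["linker"], seqs["complement_rna"])
        duplexes = [DuplexSpec("linker", "complement", association_constant(ov), ov)]
    eff = np.empty_like(traj.rna)
    for i, r in enumerate(traj.rna):
        pool = HybridPool(linker=float(r), complement=complement_tot)
        eff[i] = effective_linker(equilibrate(pool, duplexes))
    return RnaTrajectory(times=traj.times.copy(), rna=eff, ntp=None if traj.ntp is None else traj.ntp.copy())


def blocking_factor(pool: HybridPool, duplexes: Iterable[DuplexSpec]) -> float:
    """Bridging-capacity multiplier in [0, 1] left after fragment blocking.

    Degradation fragments occupy docking strands at equilibrium; bridging
    requires a free docking strand on each colloid type, so the multiplier is
    1 minus the fragment-occupied fraction of the more-blocked docking species.
    """
    if pool.docking_a <= 0 and pool.docking_b <= 0:
        raise ValueError("at least one docking total must be > 0")
    part = equilibrate(pool, duplexes)
    occ = 0.0
    for frag, dock, total in (
        ("fragment_a", "docking_a", pool.docking_a),
        ("fragment_b", "docking_b", pool.docking_b),
    ):
        if total > 0:
            c = part.duplex.get((frag, dock), part.duplex.get((dock, frag), 0.0))
            occ = max(occ, c / total)
    return 1.0 - occ
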