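"""Design of locked-nucleic-acid (LNA) imaging probes.

High-affinity confocal imaging probes are built from the same cores as the
low-affinity DNA-PAINT probes, with two modifications: a two-adenine 3'
anchor is appended, and a fixed number of nucleotides (default three) are
replaced by LNA analogs to raise the duplex melting temperature.  Because
LNA substitutions also strengthen any *off-target* duplex, positions are
chosen to avoid the partially complementary regions each probe shares with
non-cognate docking strands.

The optimizer enumerates every substitution scheme (``C(L, n)`` position
sets; 286 for a 13-mer with three LNAs), scores each with an empirical
cross-hybridization cost, and returns the global minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq

__all__ = [
    "ProbeSequence",
    "CrossHybRegion",
    "SchemeCost",
    "append_anchor",
    "find_cross_hyb_regions",
    "scheme_cost",
    "design_lna_scheme",
    "demo_panel",
]

_DNA_ALPHABET = frozenset("ACGT")
ANCHOR = "AA"


@dataclass(frozen=True)
class ProbeSequence:
    """An imaging-probe sequence (5'→3') with its chosen LNA positions.

    ``lna_positions`` are 0-based indices into ``sequence``; the sequence
    already includes the 3' ``AA`` anchor.
    """

    sequence: str
    cognate_id: str
    lna_positions: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(f"invalid nucleotides {sorted(bad)} in probe sequence")
        if len(set(self.lna_positions)) != len(self.lna_positions):
            raise ValueError("duplicate LNA positions")
        for p in self.lna_positions:
            if not 0 <= p < len(self.sequence):
                raise ValueError(f"LNA position {p} outside sequence of length {len(self.sequence)}")


@dataclass(frozen=True)
class CrossHybRegion:
    """A maximal ungapped complementary stretch between probe and docking strand.

    Intervals are 0-based half-open: ``probe_interval`` indexes the probe
    sequence, ``docking_interval`` the docking strand, both 5'→3'.
    """

    docking_id: str
    probe_interval: tuple[int, int]
    docking_interval: tuple[int, int]

    @property
    def length(self) -> int:
        return self.probe_interval[1] - self.probe_interval[0]


@dataclass(frozen=True)
class SchemeCost:
    """Cost of one substitution scheme: max over docking strands of per-strand costs."""

    per_strand: dict[str, float]

    @property
    def assigned(self) -> float:
        return max(self.per_strand.values()) if self.per_strand else 0.0


def append_anchor(core: str, cognate_id: str = "") -> ProbeSequence:
    """Append the two-adenine 3' anchor to a probe core sequence."""
    if not core:
        raise ValueError("empty probe core sequence")
    bad = set(core) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)} in probe core")
    return ProbeSequence(sequence=core + ANCHOR, cognate_id=cognate_id)


def _complement(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"C", "G"})


def find_cross_hyb_regions(
    probe: ProbeSequence,
    docking_strands: dict[str, str],
    min_len: int = 4,
    exclude_cognate_duplex: bool = True,
) -> list[CrossHybRegion]:
    """Enumerate all maximal ungapped complementary stretches of length >= min_len.

    The probe binds a docking strand antiparallel, so a stretch where
    ``probe[i..i+L)`` equals the reverse complement of ``docking[j..j+L)``
    is a potential duplex.  At the 11-13 nt lengths involved an exhaustive
    diagonal scan over all relative offsets is exact and deterministic.

    The intended duplex — a region on the cognate strand covering the full
    docking strand — is not a cross-hybridization and is dropped when
    ``exclude_cognate_duplex`` is set.
    """
    regions: list[CrossHybRegion] = []
    p = probe.sequence
    n = len(p)
    for dock_id, dock in docking_strands.items():
        rc = str(Seq(dock).reverse_complement())
        m = len(rc)
        # scan every diagonal of the probe-vs-reverse-complement dot plot
        for offset in range(-(m - 1), n):
            k = 0  # current run length
            # positions along the diagonal: probe index i, rc index i - offset
            start_i = max(0, offset)
            end_i = min(n, m + offset)
            for i in range(start_i, end_i + 1):
                if i < end_i and p[i] == rc[i - offset]:
                    k += 1
                    continue
                if k >= min_len:
                    pi = (i - k, i)
                    # rc interval [i-k-offset, i-offset) maps back onto the
                    # docking strand reversed: dock interval is its mirror
                    di = (m - (i - offset), m - (i - k - offset))
                    reg = CrossHybRegion(dock_id, pi, di)
                    if not (
                        exclude_cognate_duplex
                        and dock_id == probe.cognate_id
                        and reg.docking_interval == (0, m)
                    ):
                        regions.append(reg)
                k = 0
    return regions


def scheme_cost(
    positions: tuple[int, ...] | list[int],
    regions: list[CrossHybRegion],
    probe_length: int,
    alpha: float = 2.0,
    beta: float = 1.0,
) -> SchemeCost:
    """Score one LNA substitution scheme against the cross-hybridization regions.

    Per docking strand ``d``:  ``cost_d = sum over regions r of d of
    length(r)**beta * n_lna_in(r)**alpha``, and the scheme is assigned the
    maximum over strands.  The cost is zero when no LNA falls inside any
    region, grows with the number of LNAs placed inside a region (exponent
    ``alpha``) and with the region length (exponent ``beta``).
    """
    pos = sorted(set(positions))
    for p in pos:
        if not 0 <= p < probe_length:
            raise ValueError(f"LNA position {p} outside probe of length {probe_length}")
    per_strand: dict[str, float] = {}
    for reg in regions:
        lo, hi = reg.probe_interval
        n_in = sum(lo <= p < hi for p in pos)
        c = (reg.length**beta) * (n_in**alpha) if n_in else 0.0
        per_strand[reg.docking_id] = per_strand.get(reg.docking_id, 0.0) + c
    return SchemeCost(per_strand=per_strand)


def design_lna_scheme(
    probe: ProbeSequence,
    docking_strands: dict[str, str],
    n_lna: int = 3,
    min_len: int = 4,
    alpha: float = 2.0,
    beta: float = 1.0,
    return_table: bool = False,
):
    """Choose the LNA positions minimizing cross-hybridization cost.

    Exhaustively enumerates all ``C(L, n_lna)`` position sets; ties are
    broken by the lexicographically smallest set.  Returns the probe with
    positions filled in and its :class:`SchemeCost`; with ``return_table``
    also the full (positions, assigned cost) list.
    """
    L = len(probe.sequence)
    if n_lna > L:
        raise ValueError(f"cannot place {n_lna} LNAs in a {L}-nt probe")
    regions = find_cross_hyb_regions(probe, docking_strands, min_len=min_len)
    best_pos: tuple[int, ...] | None = None
    best_cost: SchemeCost | None = None
    table = []
    for combo in itertools.combinations(range(L), n_lna):
        cost = scheme_cost(combo, regions, L, alpha=alpha, beta=beta)
        if return_table:
            table.append((combo, cost.assigned))
        if best_cost is None or cost.assigned < best_cost.assigned:
            best_pos, best_cost = combo, cost
        # combinations() is lexicographic, so the first minimum is the tie-winner
    designed = ProbeSequence(probe.sequence, probe.cognate_id, best_pos)
    if return_table:
        return designed, best_cost, table
    return designed, best_cost


def demo_panel() -> tuple[dict[str, str], dict[str, str]]:
    """A synthetic demonstration panel of docking strands and probe cores.

    The published docking sequences live in supplementary tables that are
    not redistributed here; this panel is invented with the same geometry
    (11-nt docking strands, probe core = exact reverse complement) purely
    to exercise the design algorithm.
    """
    docks = {
        "p1": "ATACATCTAGG",
        "p2": "TTATACATCTA",
        "p3": "GGAATGTTAGG",
        "p4": "ATGTAGGTAAA",
        "p5": "CCAATTACATC",
        "p6": "AGGAGGTATTG",
    }
    cores = {k: str(Seq(v).reverse_complement()) for k, v in docks.items()}
    return docks, cores
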