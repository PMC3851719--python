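"""Nearest-neighbor thermodynamics of fully paired RNA duplexes.

The stability of a short RNA helix at 37 °C is modeled as

    ΔG°37 = initiation + Σ_steps stack(step) + terminal penalties + symmetry

where the sum runs over adjacent base-pair steps, each end closed by an
AU, UA, GU or UG pair pays the terminal penalty, and self-complementary
duplexes pay a symmetry correction.  Two Turner parameter revisions ship
as embedded TSV tables (kcal-denominated, converted at 4.184 kJ/kcal);
the default is the turner2004 revision.

Strand orientation: the top strand is given 5'->3' and the bottom strand
3'->5', aligned position by position under the top, so ``top[i]`` pairs
``bottom[i]``.  Only Watson-Crick (AU, UA, GC, CG) and wobble (GU, UG)
pairs are allowed; anything else makes the duplex invalid.

The motivating use is the "ligand as one extra AU pair" comparison: the
stabilization a stacked ligand confers on a terminal helix equals, in this
model, the ΔΔG°37 of extending the helix by one AU pair, and initiation
cancels exactly in that difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

from .constants import KCAL_TO_KJ
from .errors import InvalidDuplexError, ParameterCoverageError

__all__ = [
    "Duplex",
    "NNParameterSet",
    "DEFAULT_PARAMETER_SET",
    "available_parameter_sets",
    "load_parameter_set",
    "parse_duplex",
    "count_pairs",
    "duplex_delta_g",
    "delta_delta_g",
]

WC_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
# ends closed by AU/UA/GU/UG pay the terminal penalty
_PENALIZED_ENDS = frozenset({"AU", "UA", "GU", "UG"})

DEFAULT_PARAMETER_SET = "turner2004"


@dataclass(frozen=True)
class Duplex:
    """A fully paired two-strand RNA duplex.

    ``top`` is 5'->3', ``bottom`` is 3'->5' aligned under it; ``pairs`` is
    the per-position list of (top base, bottom base, kind) with kind "WC"
    or "wobble".
    """

    top: str
    bottom: str
    pairs: tuple[tuple[str, str, str], ...]

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_wobble(self) -> int:
        return sum(1 for _, _, kind in self.pairs if kind == "wobble")

    def is_self_complementary(self) -> bool:
        """True when the two strands are the same molecule (top == reversed bottom)."""
        return self.top == self.bottom[::-1]

    def reversed(self) -> "Duplex":
        """End-for-end flip with strand roles swapped; ΔG°37 is invariant."""
        return parse_duplex(self.bottom[::-1], self.top[::-1])


@dataclass(frozen=True)
class NNParameterSet:
    """Nearest-neighbor table in kJ/mol with provenance.

    ``stacks`` is keyed by (top dinucleotide 5'->3', bottom dinucleotide
    3'->5'); ``initiation``, ``terminal_au`` (per affected end) and
    ``symmetry`` are the duplex-level terms.
    """

    name: str
    stacks: dict
    initiation: float
    terminal_au: float
    symmetry: float
    provenance: str

    def stack(self, top_step: str, bottom_step: str) -> float:
        try:
            return self.stacks[(top_step, bottom_step)]
        except KeyError:
            raise ParameterCoverageError(
                f"no stacking entry for step 5'{top_step}3'/3'{bottom_step}5' "
                f"in parameter set {self.name!r}"
            ) from None


def available_parameter_sets() -> tuple[str, ...]:
    return ("turner1999", "turner2004")


def load_parameter_set(name: str = DEFAULT_PARAMETER_SET) -> NNParameterSet:
    """Load an embedded parameter table, converting kcal -> kJ at 4.184."""
    if name not in available_parameter_sets():
        raise ValueError(
            f"unknown parameter set {name!r}; available: {available_parameter_sets()}"
        )
    text = (resources.files("pullfe.data") / f"nn_{name}.tsv").read_text()
    stacks: dict = {}
    misc: dict = {}
    provenance = []
    for line in text.splitlines():
        if line.startswith("#"):
            provenance.append(line.lstrip("# "))
            continue
        fields = line.split("\t")
        if not fields or fields[0] == "key":
            continue
        key, top, bottom, val = fields
        if key == "stack":
            stacks[(top, bottom)] = float(val) * KCAL_TO_KJ
        else:
            misc[key] = float(val) * KCAL_TO_KJ
    return NNParameterSet(
        name=name,
        stacks=stacks,
        initiation=misc["initiation"],
        terminal_au=misc["terminal_au"],
        symmetry=misc["symmetry"],
        provenance="; ".join(provenance[:2]),
    )


def parse_duplex(top: str, bottom: str) -> Duplex:
    """Build a duplex from a 5'->3' top strand and a 3'->5' bottom strand.

    T is auto-converted to U with a warning; a position whose bases cannot
    form a Watson-Crick or wobble pair raises :class:`InvalidDuplexError`
    naming the (1-based) position.
    """
    top_u, bottom_u = top.strip().upper(), bottom.strip().upper()
    if "T" in top_u or "T" in bottom_u:
        warnings.warn("DNA-style T converted to U", UserWarning, stacklevel=2)
        top_u, bottom_u = top_u.replace("T", "U"), bottom_u.replace("T", "U")
    for name, s in (("top", top_u), ("bottom", bottom_u)):
        bad = set(s) - set("ACGU")
        if bad:
            raise InvalidDuplexError(f"{name} strand has non-RNA characters {sorted(bad)}")
    if len(top_u) != len(bottom_u):
        raise InvalidDuplexError(
            f"strand lengths differ: {len(top_u)} vs {len(bottom_u)}"
        )
    if len(top_u) < 2:
        raise InvalidDuplexError("a duplex needs at least 2 base pairs")
    pairs = []
    for i, (a, b) in enumerate(zip(top_u, bottom_u), start=1):
        pair = a + b
        if pair in WC_PAIRS:
            pairs.append((a, b, "WC"))
        elif pair in WOBBLE_PAIRS:
            pairs.append((a, b, "wobble"))
        else:
            raise InvalidDuplexError(
                f"position {i}: {a}·{b} is neither Watson-Crick nor wobble"
            )
    return Duplex(top=top_u, bottom=bottom_u, pairs=tuple(pairs))


def count_pairs(duplex: Duplex) -> int:
    """Number of base pairs in the duplex."""
    return len(duplex)


def duplex_delta_g(duplex: Duplex, params: NNParameterSet | None = None) -> float:
    """ΔG°37 of a fully paired duplex in kJ/mol.

    Initiation + nearest-neighbor stacking over all adjacent steps +
    terminal penalty for each end closed by an AU/UA/GU/UG pair +
    symmetry correction for self-complementary duplexes.
    """
    params = params or load_parameter_set()
    dg = params.initiation
    for i in range(len(duplex) - 1):
        dg += params.stack(duplex.top[i:i + 2], duplex.bottom[i:i + 2])
    for end in (0, len(duplex) - 1):
        if duplex.top[end] + duplex.bottom[end] in _PENALIZED_ENDS:
            dg += params.terminal_au
    if duplex.is_self_complementary():
        dg += params.symmetry
    return dg


def delta_delta_g(duplex_extended: Duplex, duplex_reference: Duplex,
                  params: NNParameterSet | None = None) -> float:
    """ΔG°37(extended) - ΔG°37(reference) in kJ/mol; initiation cancels."""
    params = params or load_parameter_set()
    return duplex_delta_g(duplex_extended, params) - duplex_delta_g(duplex_reference, params)
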