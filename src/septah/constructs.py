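"""Peptide construct assembly, residue classification and net charge.

The constructs are built from four canonical segments of the Cdc12
C-terminal region: an 8-residue N-flank, the 18-residue amphipathic-helix
core, an 8-residue C-flank and a 10-residue Gly/Ser linker.  Tandem
constructs join two core domains through the linker; "CN" variants reverse
the residue order of the flipped domain (sequence reversal only, no
stereochemistry change), which makes CN-NC a palindromic arrangement.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

from .errors import InputError
from .model import ONE_TO_THREE, PeptideRegions

__all__ = [
    "N_FLANK",
    "AH_CORE",
    "C_FLANK",
    "LINKER",
    "CONSTRUCT_NAMES",
    "ConstructSpec",
    "ChargeModel",
    "build_construct",
    "net_charge",
    "classify_residue",
    "residue_class_table",
    "write_fasta",
]

N_FLANK = "ERIRLNGD"
AH_CORE = "LEEIQGKVKKLEEQVKSL"
C_FLANK = "QVKKSHLK"
LINKER = "GSGSRSGSGS"

CONSTRUCT_NAMES = (
    "extended_AH",
    "tandem_NC_NC",
    "tandem_CN_NC",
    "tandem_extended_CN_NC",
)

_CLASS_OF = {}
for _aa in "DE":
    _CLASS_OF[_aa] = "acidic"
for _aa in "KRH":
    _CLASS_OF[_aa] = "basic"
for _aa in "STNQCYG":
    _CLASS_OF[_aa] = "polar"
for _aa in "AVLIMFWP":
    _CLASS_OF[_aa] = "hydrophobic"

RESIDUE_CLASSES = ("acidic", "basic", "polar", "hydrophobic")


@dataclass(frozen=True)
class ChargeModel:
    """Integer side-chain charges at a fixed pH (default pH 7.4).

    Histidine is neutral at pH 7.4; fractional Henderson-Hasselbalch
    charges are out of scope.  Free (uncapped) termini contribute +1 (N)
    and -1 (C); neutral caps contribute nothing.
    """

    ph: float = 7.4
    side_chain: dict = field(
        default_factory=lambda: {"D": -1, "E": -1, "K": +1, "R": +1, "H": 0}
    )
    free_n_terminus: int = +1
    free_c_terminus: int = -1


@dataclass(frozen=True)
class ConstructSpec:
    name: str
    sequence: str
    regions: PeptideRegions
    n_cap: str = "neutral"      # neutral | free
    c_cap: str = "neutral"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set(ONE_TO_THREE)
        if bad:
            raise InputError(f"non-standard residue letters: {sorted(bad)}")
        self.regions.validate_length(len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


def _regions_for(sequence: str, name: str) -> PeptideRegions:
    n = len(sequence)
    if name == "extended_AH":
        return PeptideRegions()
    # Tandem constructs: keep the classifier's N/C patch semantics by
    # anchoring the patches to the construct termini.
    return PeptideRegions(
        n_patch=(1, 8),
        ah_core=(9, n - 8),
        c_patch=(n - 7, n),
        second_half=(n // 2, n),
    )


def build_construct(name: str) -> ConstructSpec:
    """Assemble a named construct from the canonical Cdc12 segments.

    extended_AH            N-flank + core + C-flank                (34 aa)
    tandem_NC_NC           core + linker + core                    (46 aa)
    tandem_CN_NC           reversed core + linker + core           (46 aa)
    tandem_extended_CN_NC  reversed (core + C-flank) + linker
                           + core + C-flank                       (62 aa)
    """
    if name == "extended_AH":
        seq = N_FLANK + AH_CORE + C_FLANK
    elif name == "tandem_NC_NC":
        seq = AH_CORE + LINKER + AH_CORE
    elif name == "tandem_CN_NC":
        seq = AH_CORE[::-1] + LINKER + AH_CORE
    elif name == "tandem_extended_CN_NC":
        seq = (AH_CORE + C_FLANK)[::-1] + LINKER + AH_CORE + C_FLANK
    else:
        raise InputError(
            f"unknown construct {name!r}; expected one of {CONSTRUCT_NAMES}"
        )
    return ConstructSpec(name=name, sequence=seq, regions=_regions_for(seq, name))


def net_charge(
    sequence: str,
    model: ChargeModel | None = None,
    n_cap: str = "neutral",
    c_cap: str = "neutral",
) -> int:
    """Sum of side-chain charges plus terminal contributions (charge units)."""
    model = model or ChargeModel()
    total = 0
    for aa in sequence:
        if aa not in ONE_TO_THREE:
            raise InputError(f"unknown residue letter {aa!r}")
        total += model.side_chain.get(aa, 0)
    if sequence:
        if n_cap == "free":
            total += model.free_n_terminus
        elif n_cap != "neutral":
            raise InputError(f"unknown n_cap {n_cap!r}")
        if c_cap == "free":
            total += model.free_c_terminus
        elif c_cap != "neutral":
            raise InputError(f"unknown c_cap {c_cap!r}")
    return total


def classify_residue(aa: str) -> str:
    """Residue class: acidic {D,E}, basic {K,R,H}, polar {S,T,N,Q,C,Y,G},
    hydrophobic {A,V,L,I,M,F,W,P}."""
    try:
        return _CLASS_OF[aa]
    except KeyError:
        raise InputError(f"unknown residue letter {aa!r}") from None


def residue_class_table(sequence: str, model: ChargeModel | None = None):
    """Per-residue (index, letter, class, side-chain charge) rows."""
    model = model or ChargeModel()
    return [
        (i + 1, aa, classify_residue(aa), model.side_chain.get(aa, 0))
        for i, aa in enumerate(sequence)
    ]


def write_fasta(specs, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for spec in specs:
            fh.write(f">{spec.name} length={len(spec)}\n")
            for k in range(0, len(spec.sequence), 60):
                fh.write(spec.sequence[k : k + 60] + "\n")


def write_class_csv(sequence: str, path: os.PathLike | str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["residue_index", "residue", "class", "side_chain_charge"])
        w.writerows(residue_class_table(sequence))
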