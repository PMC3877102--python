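"""Protein–ligand interatomic contact counting.

The feature is a 36-long vector of occurrence counts of element-pair
contacts within a 12 Å cutoff: ligand elements C, N, O, F, P, S, Cl, Br, I
against protein elements C, N, O, S.  The full ligand×protein enumeration
over the nine elements gives 81 ordered pairs; the 45 whose protein-side
element is a halogen or phosphorus are omitted (protein polymers contain
none), leaving 36.  ``C_N`` means ligand carbon against protein nitrogen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structures import MolecularStructure, Pose

LIGAND_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "F", "P", "S", "Cl", "Br", "I")
PROTEIN_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S")
#: Protein-side elements dropped from the full 9x9 enumeration.
OMITTED_PROTEIN_ELEMENTS: tuple[str, ...] = ("F", "P", "Cl", "Br", "I")

DEFAULT_CUTOFF_A: float = 12.0


def enumerate_contact_types(include_omitted: bool = False) -> list[str]:
    """Canonical ordered contact-type labels, ``<ligand>_<protein>``.

    With ``include_omitted`` the full 81-pair ligand×protein enumeration over
    the nine elements is returned; by default the 45 pairs with a
    non-polymer protein-side element are removed, leaving the 36 used as
    features.  Order is lexicographic in the element listings above
    (ligand-major), and is part of the feature schema.
    """
    protein_side = LIGAND_ELEMENTS if include_omitted else PROTEIN_ELEMENTS
    return [f"{lig}_{prot}" for lig in LIGAND_ELEMENTS for prot in protein_side]


CONTACT_TYPES: tuple[str, ...] = tuple(enumerate_contact_types())
N_CONTACT_TYPES: int = len(CONTACT_TYPES)


@dataclass
class ContactVector:
    """Counts of qualifying ligand-atom/protein-atom pairs, one per contact type."""

    counts: np.ndarray  # (36,) non-negative ints
    cutoff_A: float = DEFAULT_CUTOFF_A
    labels: tuple[str, ...] = field(default=CONTACT_TYPES, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CONTACT_TYPES,):
            raise ValueError(f"contact vector must have {N_CONTACT_TYPES} entries")
        if (self.counts < 0).any():
            raise ValueError("contact counts must be non-negative")

    def __getitem__(self, label: str) -> int:
        return int(self.counts[self.labels.index(label)])

    def as_dict(self) -> dict[str, int]:
        return {lab: int(c) for lab, c in zip(self.labels, self.counts)}


def count_contacts(
    protein: MolecularStructure,
    pose: Pose | MolecularStructure,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> ContactVector:
    """Count element-pair contacts between a protein and one ligand pose.

    A pair qualifies when its Euclidean distance is <= ``cutoff`` (inclusive).
    Hydrogens, elements outside the two canonical sets, and the protein's
    flagged hetero atoms (waters, co-factors) contribute nothing.
    """
    if protein.role != "protein":
        raise ValueError(f"expected a protein-role structure, got {protein.role!r}")
    ligand = pose.ligand if isinstance(pose, Pose) else pose
    lig_coords = ligand.require_coords()
    prot = protein.polymer_view()
    prot_coords = prot.require_coords()

    lig_elems = np.asarray(ligand.elements)
    prot_elems = np.asarray(prot.elements)

    counts = np.zeros(N_CONTACT_TYPES, dtype=np.int64)
    idx = 0
    for le in LIGAND_ELEMENTS:
        lmask = lig_elems == le
        if not lmask.any():
            idx += len(PROTEIN_ELEMENTS)
            continue
        lxyz = lig_coords[lmask]
        for pe in PROTEIN_ELEMENTS:
            pmask = prot_elems == pe
            if pmask.any():
                d = cdist(lxyz, prot_coords[pmask])
                counts[idx] = int((d <= cutoff).sum())
            idx += 1
    return ContactVector(counts=counts, cutoff_A=cutoff)
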