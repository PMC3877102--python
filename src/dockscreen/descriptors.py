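"""Molecular physicochemical descriptors of the test compound.

A fixed 74-descriptor schema in six groups (constitutional, topological,
connectivity/shape, electronic/charge, lipophilicity/solubility,
drug-likeness/surface).  The schema is an open surrogate built on RDKit:
it mirrors the grouping of classical commercial descriptor sets, is frozen
for a model's lifetime, and is shipped as JSON alongside the package.
Descriptors are computed on the input connectivity (compound-level QSAR
properties), never on a docked conformer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors as D

from .errors import EmptyStructureError
from .structures import MolecularStructure

logger = logging.getLogger(__name__)

#: (descriptor name, group) in canonical order.  74 entries, 6 groups.
DESCRIPTOR_SCHEMA: tuple[tuple[str, str], ...] = tuple(
    [
        # constitutional: composition counts, independent of geometry
        ("MolWt", "constitutional"),
        ("HeavyAtomCount", "constitutional"),
        ("NumHeteroatoms", "constitutional"),
        ("NumValenceElectrons", "constitutional"),
        ("NHOHCount", "constitutional"),
        ("NOCount", "constitutional"),
        ("RingCount", "constitutional"),
        ("NumAromaticRings", "constitutional"),
        ("NumSaturatedRings", "constitutional"),
        ("NumAliphaticRings", "constitutional"),
        ("NumRotatableBonds", "constitutional"),
        ("FractionCSP3", "constitutional"),
        # topological: graph-invariant complexity and shape indices
        ("BalabanJ", "topological"),
        ("BertzCT", "topological"),
        ("HallKierAlpha", "topological"),
        ("Kappa1", "topological"),
        ("Kappa2", "topological"),
        ("Kappa3", "topological"),
        # connectivity/shape: molecular connectivity chi indices
        ("Chi0", "connectivity_shape"),
        ("Chi0n", "connectivity_shape"),
        ("Chi0v", "connectivity_shape"),
        ("Chi1", "connectivity_shape"),
        ("Chi1n", "connectivity_shape"),
        ("Chi1v", "connectivity_shape"),
        ("Chi2n", "connectivity_shape"),
        ("Chi2v", "connectivity_shape"),
        ("Chi3n", "connectivity_shape"),
        ("Chi3v", "connectivity_shape"),
        ("Chi4n", "connectivity_shape"),
        ("Chi4v", "connectivity_shape"),
        # electronic/charge: partial charges, E-state extremes, PEOE surface bins
        ("MaxPartialCharge", "electronic_charge"),
        ("MinPartialCharge", "electronic_charge"),
        ("MaxAbsPartialCharge", "electronic_charge"),
        ("MinAbsPartialCharge", "electronic_charge"),
        ("MaxEStateIndex", "electronic_charge"),
        ("MinEStateIndex", "electronic_charge"),
        ("MaxAbsEStateIndex", "electronic_charge"),
        ("MinAbsEStateIndex", "electronic_charge"),
        ("PEOE_VSA1", "electronic_charge"),
        ("PEOE_VSA2", "electronic_charge"),
        ("PEOE_VSA3", "electronic_charge"),
        ("PEOE_VSA4", "electronic_charge"),
        ("PEOE_VSA5", "electronic_charge"),
        ("PEOE_VSA6", "electronic_charge"),
        ("PEOE_VSA7", "electronic_charge"),
        ("PEOE_VSA8", "electronic_charge"),
        ("PEOE_VSA9", "electronic_charge"),
        ("PEOE_VSA10", "electronic_charge"),
        # lipophilicity/solubility: logP, molar refractivity, logP surface bins
        ("MolLogP", "lipophilicity_solubility"),
        ("MolMR", "lipophilicity_solubility"),
        ("SlogP_VSA1", "lipophilicity_solubility"),
        ("SlogP_VSA2", "lipophilicity_solubility"),
        ("SlogP_VSA3", "lipophilicity_solubility"),
        ("SlogP_VSA4", "lipophilicity_solubility"),
        ("SlogP_VSA5", "lipophilicity_solubility"),
        ("SlogP_VSA6", "lipophilicity_solubility"),
        ("SlogP_VSA7", "lipophilicity_solubility"),
        ("SlogP_VSA8", "lipophilicity_solubility"),
        ("SlogP_VSA9", "lipophilicity_solubility"),
        ("SlogP_VSA10", "lipophilicity_solubility"),
        # drug-likeness/surface: H-bonding, polar surface, MR surface bins, QED
        ("NumHDonors", "druglikeness_surface"),
        ("NumHAcceptors", "druglikeness_surface"),
        ("TPSA", "druglikeness_surface"),
        ("LabuteASA", "druglikeness_surface"),
        ("qed", "druglikeness_surface"),
        ("SMR_VSA1", "druglikeness_surface"),
        ("SMR_VSA2", "druglikeness_surface"),
        ("SMR_VSA3", "druglikeness_surface"),
        ("SMR_VSA4", "druglikeness_surface"),
        ("SMR_VSA5", "druglikeness_surface"),
        ("SMR_VSA6", "druglikeness_surface"),
        ("SMR_VSA7", "druglikeness_surface"),
        ("SMR_VSA9", "druglikeness_surface"),
        ("SMR_VSA10", "druglikeness_surface"),
    ]
)

N_DESCRIPTORS: int = len(DESCRIPTOR_SCHEMA)
DESCRIPTOR_NAMES: tuple[str, ...] = tuple(name for name, _ in DESCRIPTOR_SCHEMA)
DESCRIPTOR_GROUPS: tuple[str, ...] = tuple(dict.fromkeys(g for _, g in DESCRIPTOR_SCHEMA))

_FUNCS = {name: getattr(D, name) for name in DESCRIPTOR_NAMES}


def descriptor_schema() -> list[tuple[str, str]]:
    """The ordered (name, group) schema; deterministic across processes."""
    return list(DESCRIPTOR_SCHEMA)


@dataclass
class DescriptorVector:
    """74 finite descriptor values aligned to the canonical schema."""

    values: np.ndarray  # (74,) float64, finite
    names: tuple[str, ...] = field(default=DESCRIPTOR_NAMES, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DESCRIPTORS,):
            raise ValueError(f"descriptor vector must have {N_DESCRIPTORS} entries")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("descriptor values must be finite after imputation")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self.names, self.values)}


def compute_descriptors(
    ligand: MolecularStructure | Chem.Mol,
    impute_values: dict[str, float] | None = None,
) -> DescriptorVector:
    """Compute the 74-descriptor vector for one compound.

    A descriptor that errors out or returns a non-finite value is imputed
    (training-set median when ``impute_values`` is supplied, 0 otherwise)
    and the imputation is logged — downstream models never see NaN.
    """
    if isinstance(ligand, MolecularStructure):
        mol = ligand.mol
        if mol is None:
            raise EmptyStructureError(
                f"structure {ligand.id!r} carries no chemical connectivity; "
                "descriptors need an RDKit molecule (SDF/Mol2/SMILES input)"
            )
    else:
        mol = ligand
    if mol.GetNumAtoms() == 0:
        raise EmptyStructureError("cannot compute descriptors for an empty molecule")

    values = np.empty(N_DESCRIPTORS, dtype=float)
    for i, name in enumerate(DESCRIPTOR_NAMES):
        try:
            v = float(_FUNCS[name](mol))
        except Exception as exc:  # RDKit raises a zoo of exception types
            logger.warning("descriptor %s failed (%s); imputing", name, exc)
            v = math.nan
        if not math.isfinite(v):
            v = (impute_values or {}).get(name, 0.0)
            logger.info("descriptor %s non-finite; imputed %.4g", name, v)
        values[i] = v
    return DescriptorVector(values=values)
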