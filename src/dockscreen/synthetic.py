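"""Synthetic fixtures with known ground truth.

The generators stand in for licensed benchmark data: element-labelled
point-cloud "complexes" with countable contacts, training tables whose
affinity is a known smooth function of a few contact features, pose
triples in which the best tool is predictable from the features, and a
small EGFR-style pathway model (14 proteins, 27 reactions).  The point
clouds are not chemically valid polymers — they exist to exercise contact
counting, the learning systems and the file parsers, not docking physics.

Everything is deterministic given (recipe, seed).
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem

from .contacts import (
    CONTACT_TYPES,
    DEFAULT_CUTOFF_A,
    LIGAND_ELEMENTS,
    N_CONTACT_TYPES,
    PROTEIN_ELEMENTS,
    ContactVector,
)
from .descriptors import DescriptorVector, compute_descriptors
from .mode_selection import Candidate, CandidateTriple
from .rescoring import INACTIVE_PKD, TOOL_PRIORITY, TrainingExample
from .structures import MolecularStructure, Pose, write_pdb, write_poses_sdf

#: 50 small drug-like molecules (SMILES) cycled deterministically when a
#: fixture needs real chemistry for the descriptor block.
FIXTURE_SMILES: tuple[str, ...] = (
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(C)Cc1ccc(cc1)C(C)C(=O)O",       # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "c1ccc2c(c1)cccc2O",                # naphthol
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",       # procainamide
    "NC(=O)c1ccc(N)cc1",                # aminobenzamide
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "Clc1ccc(cc1)C(c1ccccc1)N1CCCC1",   # chlorinated amine
    "COc1ccc2cc(ccc2c1)C(C)C(=O)O",     # naproxen
    "CC1=CC(=O)C=CC1=O",                # methylquinone
    "Nc1ncnc2[nH]cnc12",                # adenine
    "O=c1[nH]cnc2[nH]ncc12",            # allopurinol
    "OCC1OC(O)C(O)C(O)C1O",             # glucose
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "CN1CCC[C@H]1c1cccnc1",             # nicotine
    "OC(=O)CCc1ccccc1",                 # phenylpropionate
    "CC(N)Cc1ccccc1",                   # amphetamine
    "NS(=O)(=O)c1ccc(N)cc1",            # sulfanilamide
    "Fc1ccc(cc1)C(=O)c1ccccc1",         # fluorobenzophenone
    "Brc1ccccc1C(=O)O",                 # bromobenzoate
    "Ic1ccc(O)cc1",                     # iodophenol
    "CSCCC(N)C(=O)O",                   # methionine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",      # tryptophan
    "NC(Cc1ccc(O)cc1)C(=O)O",           # tyrosine
    "OC(=O)C1CCCN1",                    # proline
    "NC(=N)NCCCC(N)C(=O)O",             # arginine
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citrate
    "CC(=O)NC1C(O)OC(CO)C(O)C1O",       # GlcNAc
    "c1ccc(cc1)c1ccccc1",               # biphenyl
    "O=C(Nc1ccccc1)c1ccccc1",           # benzanilide
    "CN(C)c1ccc(cc1)N=Nc1ccccc1",       # azo dye
    "CCOC(=O)c1ccccc1N",                # benzocaine analogue
    "CC(C)NCC(O)COc1ccccc1",            # propranolol fragment
    "OCCN1CCN(CC1)c1ccccc1",            # phenylpiperazine
    "O=C1CCCCC1",                       # cyclohexanone
    "C1CCNCC1",                         # piperidine
    "c1ccsc1",                          # thiophene
    "c1ccoc1",                          # furan
    "c1cc[nH]c1",                       # pyrrole
    "c1ccncc1",                         # pyridine
    "Clc1cccc(Cl)c1",                   # dichlorobenzene
    "CC(C)(C)c1ccc(O)cc1",              # tert-butylphenol
    "CCCCCCCCC(=O)O",                   # nonanoate
    "OC(=O)c1cc(O)c(O)c(O)c1",          # gallate
    "COc1cc(C=CC(=O)O)ccc1O",           # ferulate
    "CN1CCN(CC1)C(=O)c1ccccc1",         # benzoylpiperazine
    "O=S(=O)(N)c1ccc2c(c1)nccc2",       # quinoline sulfonamide
    "NCCS",                             # cysteamine
    "CC(=O)SCCNC(=O)C",                 # acetyl thioester
)


@dataclass
class FixtureRecipe:
    """Serializable description of a fixture family; same recipe + seed ⇒ same bytes."""

    n_complexes: int = 100
    n_protein_atoms: int = 40
    n_ligand_atoms: int = 12
    box_edge_A: float = 16.0
    protein_elements: tuple[str, ...] = PROTEIN_ELEMENTS
    ligand_elements: tuple[str, ...] = LIGAND_ELEMENTS + ("H",)
    cutoff_A: float = DEFAULT_CUTOFF_A
    # affinity function: label = intercept + coeffs·standardized(selected counts)
    # + interaction·z0·z1 + N(0, sigma), clipped to [1, 12]
    affinity_intercept: float = 6.5
    affinity_coeffs: tuple[float, ...] = (1.2, -0.9, 0.7, 0.5, -0.6)
    affinity_features: tuple[int, ...] = (0, 1, 2, 3, 5)
    affinity_interaction: float = 0.4
    noise_sigma: float = 0.0
    contact_rate: float = 8.0  # Poisson mean of each contact count
    fraction_inactive: float = 0.0
    # best-tool rule: class index = number of rule thresholds below the
    # designated feature (contact index in the designated tool's slot)
    rule_feature: int = 0
    rule_slot: str = "eHiTS"
    rule_thresholds: tuple[float, ...] = (6.0, 9.0)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


# ---------------------------------------------------------------------------
# Independent contact oracle (plain double loop, no vectorization)
# ---------------------------------------------------------------------------


def brute_force_contacts(
    protein: MolecularStructure,
    ligand: MolecularStructure,
    cutoff: float = DEFAULT_CUTOFF_A,
) -> ContactVector:
    """Reference O(n·m) pair enumeration used to check the fast counter."""
    index = {label: i for i, label in enumerate(CONTACT_TYPES)}
    counts = [0] * N_CONTACT_TYPES
    prot_coords = protein.require_coords()
    lig_coords = ligand.require_coords()
    for li, le in enumerate(ligand.elements):
        for pi, pe in enumerate(protein.elements):
            if protein.is_hetero[pi]:
                continue
            label = f"{le}_{pe}"
            if label not in index:
                continue
            dx = lig_coords[li][0] - prot_coords[pi][0]
            dy = lig_coords[li][1] - prot_coords[pi][1]
            dz = lig_coords[li][2] - prot_coords[pi][2]
            if (dx * dx + dy * dy + dz * dz) ** 0.5 <= cutoff:
                counts[index[label]] += 1
    return ContactVector(counts=np.array(counts), cutoff_A=cutoff)


# ---------------------------------------------------------------------------
# Toy complexes
# ---------------------------------------------------------------------------


def make_toy_complex(
    recipe: FixtureRecipe, seed: int
) -> tuple[MolecularStructure, Pose, ContactVector]:
    """One random point-cloud complex plus its brute-force expected contacts.

    Atoms are placed uniformly in a box sized so that both populated and
    empty contact types occur.
    """
    rng = np.random.default_rng(seed)
    prot_elems = list(rng.choice(recipe.protein_elements, size=recipe.n_protein_atoms))
    lig_elems = list(rng.choice(recipe.ligand_elements, size=recipe.n_ligand_atoms))
    L = recipe.box_edge_A
    protein = MolecularStructure(
        id=f"toy-protein-{seed}",
        elements=[str(e) for e in prot_elems],
        coords=rng.uniform(0, L, size=(recipe.n_protein_atoms, 3)),
        role="protein",
    )
    ligand = MolecularStructure(
        id=f"toy-ligand-{seed}",
        elements=[str(e) for e in lig_elems],
        coords=rng.uniform(0, L, size=(recipe.n_ligand_atoms, 3)),
        role="ligand",
    )
    pose = Pose(ligand=ligand, tool="eHiTS", native_score=None, rank_in_tool=1)
    expected = brute_force_contacts(protein, ligand, recipe.cutoff_A)
    return protein, pose, expected


def write_manifest_fixture(
    recipe: FixtureRecipe,
    seed: int,
    directory: str | Path,
    tools: Sequence[str] = TOOL_PRIORITY,
    poses_per_tool: int = 3,
    shuffle_on_disk: bool = True,
) -> Path:
    """Write a complete on-disk pose-set fixture: PDB + per-tool SDF + manifest.

    Pose records are optionally shuffled on disk (ranks carried as SDF
    properties) so readers must restore rank order themselves.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    protein, _, _ = make_toy_complex(recipe, seed)
    write_pdb(protein, directory / "protein.pdb")

    manifest = {"protein": "protein.pdb", "tools": {}}
    for t_i, tool in enumerate(tools):
        poses = []
        for rank in range(1, poses_per_tool + 1):
            _, pose, _ = make_toy_complex(recipe, seed + 1000 * (t_i + 1) + rank)
            pose = Pose(
                ligand=pose.ligand,
                tool=tool,
                native_score=float(rng.uniform(-12, -4)),
                rank_in_tool=rank,
            )
            poses.append(pose)
        if shuffle_on_disk:
            poses = [poses[i] for i in rng.permutation(len(poses))]
        fname = f"poses_{tool}.sdf"
        write_poses_sdf(poses, directory / fname)
        manifest["tools"][tool] = {"path": fname, "format": "sdf"}
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


# ---------------------------------------------------------------------------
# Training sets with a known feature → affinity map
# ---------------------------------------------------------------------------

_DESCRIPTOR_CACHE: dict[str, DescriptorVector] = {}


def fixture_descriptors(i: int) -> DescriptorVector:
    """Descriptor vector of the i-th (cycled) bundled molecule, memoized."""
    smiles = FIXTURE_SMILES[i % len(FIXTURE_SMILES)]
    if smiles not in _DESCRIPTOR_CACHE:
        _DESCRIPTOR_CACHE[smiles] = compute_descriptors(Chem.MolFromSmiles(smiles))
    return _DESCRIPTOR_CACHE[smiles]


def _affinity(recipe: FixtureRecipe, counts: np.ndarray) -> float:
    lam = recipe.contact_rate
    z = (counts[list(recipe.affinity_features)] - lam) / np.sqrt(lam)
    value = recipe.affinity_intercept + float(np.dot(recipe.affinity_coeffs, z))
    value += recipe.affinity_interaction * z[0] * z[1]
    return value


@dataclass
class TrainingTruth:
    """Ground-truth record stored alongside a generated training set."""

    recipe: FixtureRecipe
    seed: int
    labels: list[float]
    n_inactive: int


def make_training_set(
    recipe: FixtureRecipe, seed: int
) -> tuple[list[TrainingExample], TrainingTruth]:
    """A labelled training table whose affinity is a known function of contacts.

    Contact counts are Poisson draws; descriptors come from the bundled
    molecule list; labels are the recipe's affinity function plus Gaussian
    noise, clipped to [1, 12].  A ``fraction_inactive`` subset is relabelled
    to the inactive dummy value pKd = 1.
    """
    rng = np.random.default_rng(seed)
    n = recipe.n_complexes
    n_inactive = int(round(n * recipe.fraction_inactive))
    inactive_rows = set(rng.choice(n, size=n_inactive, replace=False).tolist())

    examples: list[TrainingExample] = []
    labels: list[float] = []
    for i in range(n):
        counts = rng.poisson(recipe.contact_rate, size=N_CONTACT_TYPES)
        contact = ContactVector(counts=counts, cutoff_A=recipe.cutoff_A)
        desc = fixture_descriptors(i)
        if i in inactive_rows:
            label, active = INACTIVE_PKD, False
        else:
            label = _affinity(recipe, counts)
            if recipe.noise_sigma > 0:
                label += rng.normal(0.0, recipe.noise_sigma)
            label = float(np.clip(label, 1.0, 12.0))
            active = True
        examples.append(TrainingExample(contact, desc, label, active=active))
        labels.append(label)
    return examples, TrainingTruth(recipe=recipe, seed=seed, labels=labels, n_inactive=n_inactive)


# ---------------------------------------------------------------------------
# Pose triples with a known best tool
# ---------------------------------------------------------------------------


@dataclass
class TripleTruth:
    recipe: FixtureRecipe
    seed: int
    labels: list[str]
    experimental_pkd: list[float]


def make_pose_triples(
    recipe: FixtureRecipe, seed: int, tools: Sequence[str] = TOOL_PRIORITY
) -> tuple[list[CandidateTriple], TripleTruth]:
    """Labelled candidate triples in which the best tool follows a feature rule.

    The designated feature (``rule_feature`` in the ``rule_slot`` tool's
    contact vector) determines the best-tool class via the rule thresholds;
    the best tool's candidate additionally shows elevated counts in two
    signature contact types, and its simulated re-score is the one closest
    to the experimental affinity — so ``label_best_mode`` recovers the same
    label the rule assigned.
    """
    rng = np.random.default_rng(seed)
    slot_idx = list(tools).index(recipe.rule_slot)
    triples: list[CandidateTriple] = []
    labels: list[str] = []
    pkds: list[float] = []
    for i in range(recipe.n_complexes):
        per_tool_counts = [
            rng.poisson(recipe.contact_rate, size=N_CONTACT_TYPES) for _ in tools
        ]
        g = per_tool_counts[slot_idx][recipe.rule_feature]
        best_idx = bisect_left(list(recipe.rule_thresholds), g)
        best_idx = min(best_idx, len(tools) - 1)
        # signature enrichment makes the class recoverable from the joint encoding
        per_tool_counts[best_idx][1] += 6
        per_tool_counts[best_idx][2] += 6

        pkd = float(rng.uniform(2.0, 11.0))
        scores = []
        for t_i in range(len(tools)):
            if t_i == best_idx:
                offset = float(rng.uniform(-0.3, 0.3))
            else:
                offset = float(rng.uniform(0.8, 2.0)) * (1 if rng.random() < 0.5 else -1)
            scores.append(pkd + offset)

        triples.append(
            CandidateTriple(
                candidates=[
                    Candidate(
                        tool=tool,
                        contact=ContactVector(counts=per_tool_counts[t_i], cutoff_A=recipe.cutoff_A),
                        rescore=scores[t_i],
                    )
                    for t_i, tool in enumerate(tools)
                ],
                descriptors=fixture_descriptors(i),
            )
        )
        labels.append(tools[best_idx])
        pkds.append(pkd)
    return triples, TripleTruth(recipe=recipe, seed=seed, labels=labels, experimental_pkd=pkds)


# ---------------------------------------------------------------------------
# Pathway-model fixture
# ---------------------------------------------------------------------------

EGFR_SPECIES: tuple[str, ...] = (
    "EGF", "EGFR", "Shc", "Grb2", "SOS", "Ras", "Raf1",
    "PAK", "Src", "MEK", "ERK", "RSK2", "CREB", "cMyc",
)
N_EGFR_REACTIONS: int = 27


def make_egfr_network(path: str | Path) -> Path:
    """Write a small EGFR-style SBML Level 2 model: 14 proteins, 27 reactions.

    The wiring is a deterministic simplification of canonical EGFR
    signalling (receptor → adaptor → Ras/Raf → MEK/ERK → nuclear factors);
    it exists to exercise SBML species reading and score projection.
    """
    species_xml = "\n".join(
        f'        <species id="s{i + 1}" name="{name}" compartment="cell"/>'
        for i, name in enumerate(EGFR_SPECIES)
    )
    reactions = []
    n_sp = len(EGFR_SPECIES)
    for k in range(N_EGFR_REACTIONS):
        src = k % n_sp + 1
        dst = (k + 1 + k // n_sp) % n_sp + 1
        reactions.append(
            f'        <reaction id="r{k + 1}" reversible="false">\n'
            f'          <listOfReactants><speciesReference species="s{src}"/></listOfReactants>\n'
            f'          <listOfProducts><speciesReference species="s{dst}"/></listOfProducts>\n'
            f"        </reaction>"
        )
    doc = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        '<sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">\n'
        '  <model id="egfr_toy" name="EGFR signalling (synthetic fixture)">\n'
        "    <listOfCompartments>\n"
        '      <compartment id="cell" size="1"/>\n'
        "    </listOfCompartments>\n"
        "    <listOfSpecies>\n"
        f"{species_xml}\n"
        "    </listOfSpecies>\n"
        "    <listOfReactions>\n"
        + "\n".join(reactions)
        + "\n    </listOfReactions>\n"
        "  </model>\n"
        "</sbml>\n"
    )
    path = Path(path)
    path.write_text(doc)
    return path
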