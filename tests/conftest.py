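"""Shared fixtures: small trained models and on-disk pose-set fixtures.

Everything is generated programmatically at session start; nothing binary
is checked in.
"""

import pytest

from dockscreen.mode_selection import train_selector
from dockscreen.rescoring import train_rescorer
from dockscreen.structures import PoseSetManifest, ligand_from_smiles
from dockscreen.synthetic import (
    FixtureRecipe,
    make_pose_triples,
    make_training_set,
    write_manifest_fixture,
)


@pytest.fixture(scope="session")
def small_training_set():
    recipe = FixtureRecipe(n_complexes=300, noise_sigma=0.0)
    return make_training_set(recipe, seed=7)


@pytest.fixture(scope="session")
def model_a(small_training_set):
    examples, _ = small_training_set
    return train_rescorer(examples, seed=1, n_estimators=60)


@pytest.fixture(scope="session")
def labelled_triples():
    recipe = FixtureRecipe(n_complexes=400)
    return make_pose_triples(recipe, seed=3)


@pytest.fixture(scope="session")
def model_b(labelled_triples):
    triples, truth = labelled_triples
    return train_selector(triples[:300], truth.labels[:300], seed=0)


@pytest.fixture(scope="session")
def manifest_dir(tmp_path_factory):
    directory = tmp_path_factory.mktemp("manifest")
    path = write_manifest_fixture(FixtureRecipe(), seed=11, directory=directory)
    return path.parent


@pytest.fixture(scope="session")
def manifest(manifest_dir):
    return PoseSetManifest.from_json(manifest_dir / "manifest.json")


@pytest.fixture(scope="session")
def aspirin():
    return ligand_from_smiles("CC(=O)Oc1ccccc1C(=O)O", "aspirin")
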