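import pytest

import cyp21stab as cs


@pytest.fixture(scope="session")
def toy_context(tmp_path_factory):
    """Toy structure: residues at controlled distances/orientations from heme.

    1: LEU at 4.31 Å pointing towards the heme (known contact geometry),
    2: ALA at 20 Å (far), 3: ARG at exactly 5.0 Å towards (boundary),
    4: VAL at 4.0 Å pointing away (orientation test must reject).
    """
    pdb = cs.generate_toy_structure(
        [
            ("LEU", 4.31, True),
            ("ALA", 20.0, True),
            ("ARG", 5.0, True),
            ("VAL", 4.0, False),
        ],
        seed=0,
    )
    path = tmp_path_factory.mktemp("fixtures") / "toy.pdb"
    path.write_text(pdb)
    return cs.load_structure(path)


@pytest.fixture(scope="session")
def survey_fit_set():
    from cyp21stab.datasets import calibration_fit_set

    return calibration_fit_set()


@pytest.fixture(scope="session")
def survey_model(survey_fit_set):
    return cs.fit_calibration(survey_fit_set, n_perm=500, seed=11)
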