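import pytest

import pepdigest as pg


@pytest.fixture(scope="session")
def caseins():
    return pg.bundled_caseins()


@pytest.fixture(scope="session")
def beta_casein(caseins):
    return next(p for p in caseins if p.protein_id == "CASB_BOVIN")


@pytest.fixture(scope="session")
def study():
    """One synthetic two-substrate study (seed 1), mapped onto the caseins."""
    table, casein_truth, hydro_truth = pg.simulate_study(seed=1)
    observations = [pg.PeptideObservation(**row) for row in table.to_dict("records")]
    mapped, report = pg.map_observations(observations, pg.bundled_caseins())
    return {
        "table": table,
        "observations": observations,
        "mapped": mapped,
        "report": report,
        "casein_truth": casein_truth,
        "hydro_truth": hydro_truth,
    }


@pytest.fixture(scope="session")
def mapped_study(study):
    return study["mapped"]


def make_obs(sequence, intensity=1.0, substrate="casein", time_min=5, animal_id="pig1",
             protein_id=None, start=None, end=None):
    return pg.PeptideObservation(
        sequence=sequence, intensity=intensity, substrate=substrate,
        time_min=time_min, animal_id=animal_id,
        protein_id=protein_id, start=start, end=end,
    )
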