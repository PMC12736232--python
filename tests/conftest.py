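import pytest

import pdtdepth as pdt


@pytest.fixture(scope="session")
def gray_table():
    return pdt.reference_transmission_table("gray")


@pytest.fixture(scope="session")
def white_table():
    return pdt.reference_transmission_table("white")


@pytest.fixture(scope="session")
def gray_model(gray_table):
    return pdt.fit_attenuation(gray_table)


@pytest.fixture(scope="session")
def white_model(white_table):
    return pdt.fit_attenuation(white_table)


@pytest.fixture(scope="session")
def models(white_model, gray_model):
    return {"white": white_model, "gray": gray_model}


@pytest.fixture(scope="session")
def noise_free_records(models):
    return pdt.generate_study(models=models, noise_cv=0.0)


@pytest.fixture(scope="session")
def noise_free_normalized(noise_free_records):
    return pdt.normalize_viability(noise_free_records)


@pytest.fixture(scope="session")
def default_grids():
    design = pdt.StudyDesign()
    return {t: design.grid(t) for t in design.tissues}


@pytest.fixture(scope="session")
def noise_free_profiles(noise_free_normalized, default_grids):
    return pdt.profiles_from_normalized(noise_free_normalized, default_grids)
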