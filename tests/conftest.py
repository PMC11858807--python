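import pytest

from kinanthro.anthropometry import AnthropometricProfile
from kinanthro.somatotype import Somatotype

# Published group-mean somatotypes of the four orienteering study groups
GROUP_MEAN_SOMATOTYPES = {
    "elite_male": Somatotype(2.1, 4.4, 3.3),
    "non_elite_male": Somatotype(2.9, 4.5, 2.4),
    "elite_female": Somatotype(3.3, 3.5, 3.0),
    "non_elite_female": Somatotype(3.9, 4.7, 1.9),
}

GROUP_LABELS = {
    "elite_male": "ectomorphic mesomorph",
    "non_elite_male": "balanced mesomorph",
    "elite_female": "central",
    "non_elite_female": "endomorphic mesomorph",
}


@pytest.fixture
def elite_male_profile() -> AnthropometricProfile:
    """Profile built from the elite-male group means (breadths: defaults)."""
    return AnthropometricProfile(
        body_mass=65.0, stature=175.1, sitting_height=103.0, arm_span=176.1,
        pectoral=6.4, triceps=7.0, subscapular=8.4, biceps=3.3,
        suprailiac=11.0, supraspinale=7.0, abdominal=10.1,
        front_thigh=9.2, medial_calf=5.9,
        neck=35.1, relaxed_arm=27.3, flexed_arm=29.1, chest=90.3,
        waist=74.2, hip=91.2, mid_thigh=51.0, calf=37.2, ankle=22.2,
        biepicondylar_humerus=7.0, bistyloid=5.6,
        biepicondylar_femur=9.5, bimalleolar=7.2,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort at the study's group sizes (13/17/10/18), seeded."""
    from kinanthro.simulate import generate_cohort, table1_default_specs

    return generate_cohort(table1_default_specs(), seed=20230714)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    paths = small_cohort.write(out)
    return paths
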