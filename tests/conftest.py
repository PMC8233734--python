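import numpy as np
import pytest

import hepatokit as hk


@pytest.fixture(scope="session")
def pet_schedule():
    return hk.build_schedule(hk.PET_FRAME_SPEC, modality="PET")


@pytest.fixture(scope="session")
def planar_schedule():
    return hk.build_schedule(hk.PLANAR_FRAME_SPEC, modality="planar")


@pytest.fixture(scope="session")
def arterial_model():
    return hk.synthesize_arterial()


@pytest.fixture(scope="session")
def wt_erlotinib_params():
    kin = hk.GROUP_KINETICS["erlotinib"]["wild-type"]
    return hk.HepaticParams(
        cl1=kin["cl1"][0], k2=kin["k2"][0], k3=kin["k3"][0],
        k_pv=2.0, v_liver=1.5,
    )


@pytest.fixture(scope="session")
def noiseless_erlotinib_animal(wt_erlotinib_params):
    """One noise-free wild-type PET animal at the group-mean truth."""
    spec = hk.scenario("erlotinib", noise_frac=0.0, n_wt=1, n_ko=1, seed=7)
    rng = np.random.default_rng(7)
    return hk.generate_animal(
        spec, wt_erlotinib_params, rng, animal_id="WT-ref", group="wild-type"
    )


@pytest.fixture(scope="session")
def small_noisy_study():
    """Tiny noisy two-group erlotinib study for pipeline-level tests."""
    spec = hk.scenario("erlotinib", n_wt=2, n_ko=2, noise_frac=0.05, seed=11)
    return hk.generate_study(spec)


@pytest.fixture(scope="session")
def recovery_erlotinib_wt():
    """20 noisy single-animal replicates at the wild-type erlotinib truth."""
    return hk.recovery_experiment("erlotinib", "wild-type", n_replicates=20,
                                  noise_frac=0.10, base_seed=1)


@pytest.fixture(scope="session")
def recovery_mebrofenin_ko():
    """20 noisy single-animal replicates at the knockout mebrofenin truth."""
    return hk.recovery_experiment("mebrofenin", "knockout", n_replicates=20,
                                  noise_frac=0.10, base_seed=1)
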