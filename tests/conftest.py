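import warnings

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# arviz emits a refactor notice on import; irrelevant to the checks here
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def small_network():
    """A 40-trial synthetic network with fixed modality effects (tau = 0.1)."""
    from exdose.effects import build_contrasts
    from exdose.simulate import GeneratorConfig, generate_network

    cfg = GeneratorConfig(effect_model="modality", n_trials=40, tau=0.1)
    arms, metas, ledger = generate_network(cfg, seed=3)
    by_study = {}
    for a in arms:
        by_study.setdefault(a.study_id, []).append(a)
    contrasts = [
        c for sid in sorted(by_study) for c in build_contrasts(by_study[sid])
    ]
    return {"arms": arms, "metas": metas, "ledger": ledger, "contrasts": contrasts}


@pytest.fixture(scope="session")
def nma_posterior(small_network):
    from exdose.nma import NmaSpec, fit_consistency

    spec = NmaSpec(chains=2, draws=1200, warmup=600, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_consistency(small_network["contrasts"], spec)
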