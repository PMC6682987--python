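import numpy as np
import pandas as pd
import pytest

from dietscore.dds import compute_dds
from dietscore.dqs import assign_all_quintiles, compute_dqs
from dietscore.synthetic import GeneratorSpec, generate_population
from dietscore.usual import build_usual_table


@pytest.fixture(scope="session")
def medium_population():
    """1920 subjects (10 per cell), two recalls each, with latent truth."""
    spec = GeneratorSpec(subjects_per_cell=10, seed=11)
    return generate_population(spec)


@pytest.fixture(scope="session")
def medium_scores(medium_population):
    """Usual intake, quintiles, DQS and DDS for the medium population."""
    subjects, recalls, truth = medium_population
    usual, meta = build_usual_table(subjects, recalls)
    quintiles = assign_all_quintiles(usual, subjects)
    dqs = compute_dqs(quintiles)
    dds = compute_dds(recalls, scheme="wdds9")
    return {
        "subjects": subjects,
        "recalls": recalls,
        "truth": truth,
        "usual": usual,
        "usual_meta": meta,
        "quintiles": quintiles,
        "dqs": dqs,
        "dds": dds,
    }


def two_day_subgroup(n, seed, mean=50.0, sd=20.0, cv=0.3):
    """One synthetic subgroup: latent lognormal usual intake, two noisy days."""
    rng = np.random.default_rng(seed)
    s2 = np.log1p((sd / mean) ** 2)
    latent = rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), n)
    sn2 = np.log1p(cv**2)
    noise = rng.lognormal(-sn2 / 2, np.sqrt(sn2), 2 * n)
    sids = np.repeat([f"S{i:05d}" for i in range(n)], 2)
    days = pd.DataFrame({"subject_id": sids, "value": np.repeat(latent, 2) * noise})
    return days, latent
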