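import dataclasses

import numpy as np
import pandas as pd
import pytest

from ccamode import GeneratorConfig, PhenotypeTable, generate_cohort
from ccamode.synthetic import strengths_for_canonical_correlation


def make_table(values, ids=None, blocks=None, subdomains=None, polarity=None):
    """Small PhenotypeTable from a plain array."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = ids or [f"S{i:03d}" for i in range(n)]
    names = [f"v{j}" for j in range(p)]
    manifest = pd.DataFrame(
        {
            "variable": names,
            "block": blocks or ["blockA"] * p,
            "subdomain": subdomains or ["domA"] * p,
            "polarity": polarity if polarity is not None else [1] * p,
        }
    )
    return PhenotypeTable(pd.DataFrame(values, index=pd.Index(ids, name="subject_id"), columns=names), manifest)


def small_config(seed=0, n_subjects=80, n_idp=30, n_nonidp=15, rc=None, **kw):
    """Shrunk generator config for fast tests; ``rc`` plants a population
    canonical correlation."""
    cfg = GeneratorConfig(seed=seed, n_subjects=n_subjects).with_counts(n_idp, n_nonidp)
    if rc is not None:
        mx, my = strengths_for_canonical_correlation(rc)
        kw.setdefault("mode_strength_idp", mx)
        kw.setdefault("mode_strength_nonidp", my)
    return dataclasses.replace(cfg, **kw) if kw else cfg


@pytest.fixture(scope="session")
def small_bundle():
    return generate_cohort(small_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
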