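import numpy as np
import pandas as pd
import pytest

from tmbench.filters import apply_exclusions
from tmbench.matching import MatchSpec, match_all_hospitals
from tmbench.pipeline import COMPACT_MATCH_SPEC
from tmbench.risk import fit_risk_model
from tmbench.synthetic import GeneratorConfig, generate_system
from tmbench.template import draw_candidates, select_template


@pytest.fixture(scope="session")
def small_system():
    """A small benchmarkable system, risk-fitted and filtered, with one
    selected template and per-hospital matches (shared across tests)."""
    config = GeneratorConfig(n_hospitals=8, volume_range=(950, 1500))
    cohort, profiles = generate_system(config, seed=5)
    model = fit_risk_model(cohort)
    eligible, xlog = apply_exclusions(cohort)
    candidates = draw_candidates(eligible, 300, 50, seed=0)
    template = select_template(eligible, candidates)
    spec = MatchSpec(**COMPACT_MATCH_SPEC)
    results = match_all_hospitals(eligible, template.rows(eligible), spec)
    return {
        "config": config, "cohort": cohort, "profiles": profiles,
        "model": model, "eligible": eligible, "log": xlog,
        "template": template, "spec": spec, "results": results,
    }


def toy_match_frames(template_cats, matched_cats, var="grp"):
    """Tiny template/matched frames with one categorical column."""
    t = pd.DataFrame({var: list(template_cats)})
    m = pd.DataFrame({var: list(matched_cats)})
    return t, m


def random_instance(rng, m, n, p=2):
    """Random matching instance: template m x p, pool n x p numeric."""
    t = pd.DataFrame(rng.normal(size=(m, p)), columns=[f"x{i}" for i in range(p)])
    pool = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    return t, pool


def brute_force_assignment(D):
    """Exhaustive minimum of sum(D[i, perm[i]]) over injective assignments."""
    from itertools import permutations

    m, n = D.shape
    perms = np.array(list(permutations(range(n), m)))
    totals = D[np.arange(m)[None, :], perms].sum(axis=1)
    return float(totals.min())
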