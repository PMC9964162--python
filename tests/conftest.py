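from __future__ import annotations

import pytest

from gh51kit.domains import excise_domain_alignment
from gh51kit.hmm import build_profile
from gh51kit.motifs import (
    DOMAIN_END_MOTIF,
    DOMAIN_START_MOTIF,
    CatalyticStatus,
    compile_pattern,
)
from gh51kit.simulate import SimParams, generate_family


@pytest.fixture(scope="session")
def family_bundle():
    """A noisy synthetic family shared by domain/HMM/pipeline tests."""
    params = SimParams(
        seed=7,
        n=40,
        domain_prevalence=0.9,
        catalytic_composition={
            CatalyticStatus.CANONICAL_E: 0.6,
            CatalyticStatus.SUBSTITUTED_Q: 0.4,
        },
        substitution_rate=0.05,
        indel_rate=0.01,
        decoy_fraction=0.25,
    )
    records, msa, truth = generate_family(params)
    return params, records, msa, truth


@pytest.fixture(scope="session")
def family_profile(family_bundle):
    """Profile built from the excised domain alignment of the family."""
    _, _, msa, _ = family_bundle
    excised, segments, all_gap = excise_domain_alignment(
        msa,
        compile_pattern(DOMAIN_START_MOTIF),
        compile_pattern(DOMAIN_END_MOTIF),
    )
    train = excised.take_rows([rid for rid in excised.ids if rid not in set(all_gap)])
    return build_profile(train)
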