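"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import hypothesis.strategies as st
import pytest
from hypothesis import HealthCheck, settings

from aeselect import AERecord, AETable, Arm

# Deterministic, CI-friendly hypothesis profile.
settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def fixture_table() -> AETable:
    """Two-arm trial, n=100 per arm, four AE types with known contrasts."""
    return AETable(
        "T1",
        [Arm("gabapentin", 100, is_active=True), Arm("placebo", 100)],
        [
            AERecord("dizziness", {"gabapentin": 20, "placebo": 5}),
            AERecord("headache", {"gabapentin": 6, "placebo": 6}),
            AERecord("nausea", {"gabapentin": 1, "placebo": 0}),
            AERecord("fatigue", {"gabapentin": 3, "placebo": 2}),
        ],
    )


@pytest.fixture
def three_arm_table() -> AETable:
    """Two active dose arms plus placebo (the dose-arm pooling case)."""
    return AETable(
        "T3",
        [
            Arm("drug_low", 100, is_active=True),
            Arm("drug_high", 100, is_active=True),
            Arm("placebo", 100),
        ],
        [
            AERecord("somnolence", {"drug_low": 10, "drug_high": 20, "placebo": 5}),
            AERecord("dry mouth", {"drug_low": 4, "drug_high": 9, "placebo": 1}),
        ],
    )


_TERMS = [
    "dizziness", "headache", "nausea", "fatigue", "somnolence", "dry mouth",
    "tremor", "ataxia", "diarrhoea", "rash",
]


@st.composite
def ae_tables(draw, max_terms: int = 10, max_n: int = 40) -> AETable:
    """Random small valid AETables: 2-3 arms, <=10 terms, arbitrary counts."""
    n_arms = draw(st.integers(2, 3))
    # exactly one comparator when 2 arms; 1-2 active arms when 3
    n_active = draw(st.integers(1, n_arms - 1))
    arms = []
    for i in range(n_arms):
        n = draw(st.integers(1, max_n))
        arms.append(Arm(f"arm{i}", n, is_active=i < n_active))
    n_terms = draw(st.integers(1, max_terms))
    records = []
    for t in range(n_terms):
        counts = {a.name: draw(st.integers(0, a.n)) for a in arms}
        if sum(counts.values()) == 0:
            counts[arms[0].name] = draw(st.integers(1, arms[0].n))
        records.append(AERecord(_TERMS[t], counts))
    return AETable("rand", arms, records)
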