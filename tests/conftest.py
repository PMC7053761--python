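"""Shared fixtures: small pedigrees and random test-instance generators."""

import pandas as pd
import pytest

from aspenqg.pedigree import build_pedigree


@pytest.fixture
def trio_pedigree():
    """Sire, dam and one non-inbred offspring."""
    return build_pedigree([("S1", None, None), ("D1", None, None), ("O1", "S1", "D1")])


@pytest.fixture
def halfsib_pedigree():
    """Eight dams with six polymix offspring each."""
    recs = [(f"D{i}", None, None) for i in range(8)]
    recs += [(f"O{i}_{j}", None, f"D{i}") for i in range(8) for j in range(6)]
    return build_pedigree(recs)


def random_pedigree(rng, n_founders=8, n_gen1=8, n_gen2=6):
    """Random three-generation pedigree records (non-inbred by construction:
    gen-1 parents are founders, gen-2 parents are gen-1 individuals with
    different founder parents)."""
    recs = [(f"F{i}", None, None) for i in range(n_founders)]
    gen1 = []
    for i in range(n_gen1):
        s, d = rng.choice(n_founders, size=2, replace=False)
        recs.append((f"G{i}", f"F{s}", f"F{d}"))
        gen1.append((f"G{i}", {s, d}))
    for i in range(n_gen2):
        for _ in range(40):
            a, b = rng.choice(len(gen1), size=2, replace=False)
            if not (gen1[a][1] & gen1[b][1]):
                recs.append((f"H{i}", gen1[a][0], gen1[b][0]))
                break
    return recs


def balanced_oneway(rng, n_groups=12, n_per=8, mu=10.0, s_u=1.0, s_e=1.0):
    """Balanced one-way layout with known group effects; returns (df, u)."""
    u = rng.standard_normal(n_groups) * s_u
    rows = []
    for g in range(n_groups):
        for j in range(n_per):
            rows.append({"group": f"g{g}", "y": mu + u[g] + rng.standard_normal() * s_e})
    return pd.DataFrame(rows), u
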