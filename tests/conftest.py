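"""Shared fixtures: tiny designs, on-disk MaxQuant-dialect toy tables, and
synthetic stand-in protein sequences with degrons at known coordinates."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ubiquant import AnalysisConfig, SampleDesign, make_design


@pytest.fixture
def design_2x2() -> SampleDesign:
    return make_design([("A", 2), ("B", 2)])


@pytest.fixture
def design_3g4r() -> SampleDesign:
    return make_design(
        [("DNA", 4), ("DSB", 4), ("no_His", 4)],
        background="no_His",
        target_groups=["DNA", "DSB"],
    )


@pytest.fixture
def toy_protein_groups(tmp_path, design_2x2):
    """3-row protein-groups file in the MaxQuant dialect; row 2 is a decoy."""
    rows = []
    for i, (ids, rev) in enumerate(
        [("P1;P1b", ""), ("REV__P2", "+"), ("P3", "")], start=1
    ):
        row = {"Protein IDs": ids, "Gene names": f"g{i}", "Reverse": rev,
               "Potential contaminant": "", "Only identified by site": ""}
        for j, s in enumerate(design_2x2.samples):
            row[f"LFQ intensity {s}"] = 100.0 * i + j
            row[f"iBAQ {s}"] = 10.0 * i + j
        rows.append(row)
    path = tmp_path / "proteinGroups.txt"
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def synthetic_standin_sequence(
    degron: str, start: int, length: int, seed: int
) -> str:
    """Synthetic stand-in for a reference protein sequence.

    Random background drawn from an alphabet containing none of the degron
    class residues (D/E/S/T/G/Q), so the inserted ``degron`` at 1-based
    ``start`` is the only motif occurrence. Used where the real database
    sequence is not redistributable with the test suite.
    """
    rng = np.random.default_rng(seed)
    alphabet = list("ACFHIKLMNPRVWY")
    seq = rng.choice(alphabet, size=length)
    seq[start - 1 : start - 1 + len(degron)] = list(degron)
    return "".join(seq)


@pytest.fixture
def cfg_default() -> AnalysisConfig:
    return AnalysisConfig(seed=7)
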