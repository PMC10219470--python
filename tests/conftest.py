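"""Shared fixtures: tiny hand-built tables and one mid-size synthetic survey."""

import numpy as np
import pandas as pd
import pytest

from rhizonet import synth
from rhizonet.io_tables import RANKS, UNCLASSIFIED


@pytest.fixture
def small_counts() -> pd.DataFrame:
    return pd.DataFrame(
        [[5, 0, 12, 3], [1, 7, 0, 9], [4, 4, 4, 4]],
        index=["s1", "s2", "s3"],
        columns=["OTU_1", "OTU_2", "OTU_3", "OTU_4"],
    )


@pytest.fixture
def small_taxonomy() -> pd.DataFrame:
    rows = {
        "OTU_1": ["Fungi", "Basidiomycota", "Tremellomycetes", "Tremellales",
                  "Bulleribasidiaceae", "Dioszegia"],
        "OTU_2": ["Fungi", "Basidiomycota", "Tremellomycetes", "Tremellales",
                  UNCLASSIFIED, UNCLASSIFIED],
        "OTU_3": ["Fungi", "Basidiomycota", "Tremellomycetes", "Tremellales",
                  "Bulleribasidiaceae", "Dioszegia"],
        "OTU_4": ["Fungi", UNCLASSIFIED, UNCLASSIFIED, UNCLASSIFIED,
                  UNCLASSIFIED, UNCLASSIFIED],
    }
    tax = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    tax.index.name = "otu_id"
    return tax


@pytest.fixture
def paired_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {"group": ["AP", "N", "AP"], "site": ["S1", "S1", "S2"],
         "pH": [7.5, 7.9, 7.7], "TC": [18.0, 21.0, 15.5], "TN": [1.5, 1.7, 1.4],
         "TP": [0.7, 0.8, 0.6], "AN": [11.0, 13.0, 12.0], "NN": [8.0, 7.5, 9.0],
         "AP_soil": [38.0, 44.0, 41.0]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    ).rename(columns={"AP_soil": "AP"})


@pytest.fixture(scope="session")
def survey():
    """One full-size synthetic survey (counts, taxonomy, metadata, truth)."""
    return synth.generate(synth.paper44_config(11))


def brute_spearman(x, y) -> float:
    """Rank-based Spearman oracle: Pearson of average ranks, from scratch."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
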