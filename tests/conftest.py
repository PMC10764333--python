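import numpy as np
import pandas as pd
import pytest

from marginmap import synthfix
from marginmap.slideprep import PatchSet


@pytest.fixture(scope="session")
def tumor_section():
    """Rendered single-piece section with ink, tumor and a hole."""
    spec = synthfix.random_section_spec(1, tumor=True, hole=True, rotation=0.0)
    img, gt = synthfix.make_section_image(spec)
    return img, gt


@pytest.fixture(scope="session")
def inked_section():
    spec = synthfix.random_section_spec(7, canvas=(768, 768), piece_radius=200,
                                        ink=True, rotation=0.0)
    img, gt = synthfix.make_section_image(spec)
    return img, gt


def layout_patchset(gt, patch_size=64):
    """PatchSet built straight from ground-truth patch labels (no raster)."""
    df = gt.patch_labels(patch_size, 0.5)
    df = df[~df["hole"]].reset_index(drop=True)
    recs = pd.DataFrame(
        {
            "x": df["x"], "y": df["y"], "tissue_frac": df["tissue_frac"],
            "section": -1, "piece": -1, "config": "tumor_map",
            "hole_candidate": False,
        }
    )
    return PatchSet("layout", patch_size, recs), df


def piece_agreement(assigned: PatchSet, truth_df) -> float:
    """Fraction of patches with correct section and (permutation-matched)
    piece labels."""
    from scipy.optimize import linear_sum_assignment

    sec_ok = (assigned.records["section"].to_numpy()
              == truth_df["section"].to_numpy()).mean()
    matched = 0
    for si in truth_df["section"].unique():
        m = (truth_df["section"] == si).to_numpy()
        a = truth_df.loc[m, "piece"].to_numpy()
        b = assigned.records.loc[m, "piece"].to_numpy()
        k = int(max(a.max(), b.max())) + 1
        cost = np.zeros((k, k))
        for x, y in zip(a, b):
            cost[int(x), int(y)] += 1
        r, c = linear_sum_assignment(-cost)
        matched += cost[r, c].sum()
    return min(float(sec_ok), matched / len(truth_df))
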