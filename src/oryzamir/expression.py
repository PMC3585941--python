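"""Expression profiling across the four grain-filling stages.

Counts are normalized to tags per million clean reads (TPM = count /
clean total x 1e6).  Differential expression between adjacent stages uses
the Audic-Claverie exact test on raw counts with the published filtering
conventions: a TPM of 0 is replaced by 0.01 when the partner stage is
expressed, pairs below 1 TPM in both stages are not tested, and a call
requires P < 0.01 and fold change > 2 (|log2 ratio| >= 1).  Stage
preference uses the ratio > 2 / Z > 2 rule against the other stages, and
profiles of the differentially expressed miRNAs are grouped by k-means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

TRANSITIONS = ((0, 1), (1, 2), (2, 3))


def normalize(counts: pd.DataFrame, clean_totals: dict) -> pd.DataFrame:
    """TPM per library: exact formula, no pseudo-substitution here."""
    if (counts < 0).any().any():
        raise ValueError("negative count")
    tpm = counts.astype(float).copy()
    for lib in counts.columns:
        total = clean_totals[lib]
        if total <= 0:
            raise ValueError(f"non-positive clean total for {lib}")
        tpm[lib] = counts[lib] * 1e6 / total
    return tpm


def prepare_pair(tpm_a: float, tpm_b: float):
    """(adjusted a, adjusted b, testable flag) for one stage pair."""
    a, b = tpm_a, tpm_b
    if a < 1 and b < 1:
        return a, b, False
    if a == 0:
        a = 0.01
    if b == 0:
        b = 0.01
    return a, b, True


def _ac_two_sided(x: int, n1: float, y: int, n2: float) -> float:
    # posterior predictive of y given x: NegBin(x+1, n1/(n1+n2))
    p = n1 / (n1 + n2)
    lower = stats.nbinom.cdf(y, x + 1, p)
    upper = stats.nbinom.sf(y - 1, x + 1, p)
    return min(1.0, 2.0 * min(lower, upper))


def de_test(count_a: int, total_a: float, count_b: int, total_b: float) -> float:
    """Two-sided Audic-Claverie p-value for one tag in two libraries.

    The posterior-predictive tail test is directional; the reported value
    is the average over both conditioning directions, which restores exact
    symmetry under swapping the libraries (and reduces to the plain test
    when the depths are equal).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    pa = _ac_two_sided(count_a, total_a, count_b, total_b)
    pb = _ac_two_sided(count_b, total_b, count_a, total_a)
    return min(1.0, (pa + pb) / 2.0)


@dataclass
class DEResult:
    mirna: str
    transition: str
    log2_fold_change: float
    p_value: float
    direction: str  # up / down / ns
    filtered: bool  # both TPM < 1


def call_de(counts: pd.DataFrame, clean_totals: dict,
            alpha: float = 0.01, log2fc_min: float = 1.0):
    """DE calls for every adjacent-stage transition.

    Returns ``(results_frame, tallies)`` where ``tallies`` maps transition
    label -> (significant, up, down) counts, mirroring the published
    up/down summary table.
    """
    libs = list(counts.columns)
    tpm = normalize(counts, clean_totals)
    rows = []
    tallies = {}
    for ia, ib in TRANSITIONS:
        if ib >= len(libs):
            continue
        la, lb = libs[ia], libs[ib]
        label = f"{la}->{lb}"
        n_sig = n_up = n_down = 0
        for mirna in counts.index:
            a, b, testable = prepare_pair(tpm.at[mirna, la],
                                          tpm.at[mirna, lb])
            log2fc = float(np.log2(b / a)) if testable else 0.0
            direction = "ns"
            pval = 1.0
            if testable:
                pval = de_test(int(counts.at[mirna, la]), clean_totals[la],
                               int(counts.at[mirna, lb]), clean_totals[lb])
                if pval < alpha and abs(log2fc) >= log2fc_min:
                    direction = "up" if log2fc > 0 else "down"
            rows.append(DEResult(mirna, label, log2fc, pval, direction,
                                 not testable))
            if direction == "up":
                n_up += 1
            if direction == "down":
                n_down += 1
            n_sig += direction != "ns"
        tallies[label] = (n_sig, n_up, n_down)
    frame = pd.DataFrame([r.__dict__ for r in rows])
    return frame, tallies


@dataclass
class StagePrefCall:
    mirna: str
    stage: str
    ratio: float
    z_score: float


def stage_preference(tpm: pd.DataFrame, ratio_cutoff: float = 2.0,
                     z_cutoff: float = 2.0) -> pd.DataFrame:
    """Stage-preferential miRNAs by the ratio > 2 and Z > 2 rule.

    For each stage the candidate TPM is compared with the mean of the
    other stages (zeros replaced by 0.01 before averaging); Z uses the
    sample standard deviation of the other stages.  A zero spread with a
    qualifying ratio still calls (degenerate-sd rule).
    """
    calls = []
    stages = list(tpm.columns)
    for mirna, row in tpm.iterrows():
        vals = row.to_numpy(dtype=float)
        for si, stage in enumerate(stages):
            others = np.delete(vals, si)
            others = np.where(others == 0, 0.01, others)
            mean = others.mean()
            sd = others.std(ddof=1)
            ratio = vals[si] / mean
            if ratio <= ratio_cutoff:
                continue
            if sd == 0:
                calls.append(StagePrefCall(mirna, stage, ratio, np.inf))
                continue
            z = (vals[si] - mean) / sd
            if z > z_cutoff:
                calls.append(StagePrefCall(mirna, stage, ratio, z))
    return pd.DataFrame([c.__dict__ for c in calls],
                        columns=["mirna", "stage", "ratio", "z_score"])


def cluster_profiles(tpm: pd.DataFrame, k: int = 20, seed: int = 0,
                     n_restarts: int = 100):
    """K-means over per-row standardized log2(TPM + 0.01) profiles.

    Returns ``(assignments, centroids)``; deterministic for a fixed seed.
    Raises ``ValueError`` when there are fewer profiles than clusters.
    """
    if len(tpm) < k:
        raise ValueError(f"{len(tpm)} profiles < k={k}")
    mat = np.log2(tpm.to_numpy(dtype=float) + 0.01)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    mat = (mat - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(mat)
    assignments = pd.Series(labels, index=tpm.index, name="cluster")
    return assignments, km.cluster_centers_
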