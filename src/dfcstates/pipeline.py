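"""End-to-end orchestration of the brain-state analysis.

Chains the stages in the order the method runs: sliding-window Fisher-z
connectivity per session, pooling across conditions and sessions, L1 k-means
into k brain states, similarity ranking against the structural connectome,
and the occupancy / slope summaries. For synthetic sessions the ground-truth
window labels (majority vote of the latent per-scan state over each window)
are carried along so recovery can be quantified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .brain_states import BrainStateSet, KMeansModel, kmeans_l1, pool_stacks, rank_states
from .dynamic_fc import FCWindowStack, ROITimeSeries, WindowSpec, windowed_fc
from .state_stats import occupancy, slopes_by_session
from .synthetic import StructuralConnectome, SyntheticSession

__all__ = ["StudyResult", "run_brain_state_analysis", "majority_window_labels"]


@dataclass
class StudyResult:
    """Fitted brain states plus the downstream summary tables."""

    model: KMeansModel
    states: BrainStateSet
    occupancy: pd.DataFrame
    slopes: pd.DataFrame
    stacks: list[FCWindowStack]
    true_window_labels: dict[tuple[str, str], np.ndarray]

    def condition_occupancy(self) -> pd.DataFrame:
        return self.occupancy.groupby("condition").mean()


def majority_window_labels(
    true_states: np.ndarray, window_starts: np.ndarray, width: int
) -> np.ndarray:
    """Ground-truth state per window: majority vote over the window's scans."""
    return np.array(
        [np.bincount(true_states[s : s + width]).argmax() for s in window_starts]
    )


def run_brain_state_analysis(
    sessions: list[SyntheticSession | ROITimeSeries],
    sc: StructuralConnectome,
    k: int = 7,
    window: WindowSpec | None = None,
    n_init: int = 20,
    seed: int | None = None,
) -> StudyResult:
    """Run the full dynamic-FC brain-state analysis over a set of sessions.

    Sessions from all conditions are pooled for clustering, as the analysis
    requires; states are ranked by structure-function similarity and the
    per-session occupancy and occupancy-vs-similarity slopes are computed.
    """
    window = window or WindowSpec()
    stacks: list[FCWindowStack] = []
    truth: dict[tuple[str, str], np.ndarray] = {}
    for ses in sessions:
        if isinstance(ses, SyntheticSession):
            ts = ROITimeSeries(
                ses.timeseries, tr=ses.tr, condition=ses.condition,
                session_id=ses.session_id,
            )
        else:
            ts = ses
        stack = windowed_fc(ts, window)
        stacks.append(stack)
        if isinstance(ses, SyntheticSession):
            truth[(ts.condition, ts.session_id)] = majority_window_labels(
                ses.true_states, stack.window_starts, window.width
            )

    x, index = pool_stacks(stacks)
    model = kmeans_l1(x, k=k, n_init=n_init, seed=seed)
    states = rank_states(model, sc, index)
    occ = occupancy(states.label_sequences, k)
    slopes = slopes_by_session(occ, states.similarity)
    return StudyResult(
        model=model,
        states=states,
        occupancy=occ,
        slopes=slopes,
        stacks=stacks,
        true_window_labels=truth,
    )
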