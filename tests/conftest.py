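import numpy as np
import pytest

from nirslayout import design, io, phantom


@pytest.fixture(scope="session")
def optics():
    return phantom.TABLE_OPTICAL_PROPERTIES


@pytest.fixture(scope="session")
def onion():
    """Small onion phantom shared by read-only tests."""
    cfg = phantom.PhantomConfig(radius_mm=30.0, resolution_mm=2.0)
    return phantom.build_phantom(cfg, seed=0)


@pytest.fixture(scope="session")
def slab():
    return phantom.build_slab_phantom((60, 60, 45), resolution_mm=1.0)


def fast_study_config(**overrides) -> io.StudyConfig:
    """Desk-scale study configuration for evaluation tests."""
    base = dict(
        n_subjects=4,
        n_positions=60,
        n_photons=1500,
        subject_resolution_mm=2.0,
        atlas_resolution_mm=2.0,
        n_runs=2,
        n_trials_per_task_per_run=3,
        filter_order=250,
        design_tasks=("mental_calculation", "mental_rotation"),
    )
    base.update(overrides)
    return io.StudyConfig(**base)


def mini_setup():
    """Smallest useful montage: one source, two NDCs, one SDC."""
    positions = np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0],
                          [0.0, 30.0, 0.0], [8.0, 0.0, 0.0]])
    channels = [
        {"source": 0, "detector": 1, "distance_mm": 30.0, "is_sdc": False},
        {"source": 0, "detector": 2, "distance_mm": 30.0, "is_sdc": False},
        {"source": 0, "detector": 3, "distance_mm": 8.0, "is_sdc": True},
    ]
    return design.CombinedSetup(
        optode_positions=positions,
        roles=["source", "detector", "detector", "detector"],
        channels=channels,
        memberships={("iFMRI", "mental_calculation"): [0, 1]},
        n_premerge_optodes=3)


def random_channel_instance(rng, n_optodes=30, n_channels=60):
    """Random candidate-channel instance for optimizer oracle tests."""
    chans = []
    seen = set()
    while len(chans) < n_channels:
        i, j = sorted(rng.choice(n_optodes, size=2, replace=False))
        if (i, j) in seen:
            continue
        seen.add((i, j))
        chans.append(design.Channel(
            source_index=int(i), detector_index=int(j),
            distance_mm=float(rng.uniform(25, 40)),
            sensitivity_percent=float(rng.uniform(0, 50))))
    return chans


def brute_force_best_pair(channels):
    """Exhaustive search over optode-sharing channel pairs; returns the
    maximal summed sensitivity or None when no pair shares an optode."""
    best = None
    for a_i in range(len(channels)):
        for b_i in range(a_i + 1, len(channels)):
            a, b = channels[a_i], channels[b_i]
            if len(set(a.pair) & set(b.pair)) == 1:
                tot = a.sensitivity_percent + b.sensitivity_percent
                if best is None or tot > best:
                    best = tot
    return best
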