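"""Simulation experiments validating the pipeline against planted truth.

These are the package's benchmark harnesses: community recovery of the
planted block structure on the default cohort design, and statistical power
to detect a planted group difference in switching through the full
network -> community -> flexibility -> permutation-test path.
"""

from __future__ import annotations

import numpy as np

from .community import ModularityParams, repeat_optimization
from .measures import ensemble_node_flexibility
from .networks import subject_multilayer
from .stats import permutation_test
from .synthetic import (
    GroupEffect,
    SimulationDesign,
    generate_subject,
    planted_recovery_report,
)


def planted_recovery_experiment(
    seed: int,
    window_len_s: float = 30.0,
    n_repetitions: int = 10,
    design: SimulationDesign | None = None,
) -> np.ndarray:
    """Per-layer NMI between planted blocks and detected communities.

    Runs the full default design (200 regions, 7 systems, within r = 0.6,
    between 0.1, epochs aligned to windows) through windowing, multilayer
    construction, and the community-ensemble detector, and scores recovery
    per layer with normalized mutual information averaged over repetitions.
    """
    ss = np.random.SeedSequence(seed).generate_state(2)
    if design is None:
        design = SimulationDesign(window_len_s=window_len_s, seed=int(ss[0]) % (2**31))
    ts, truth = generate_subject(design, int(ss[0]) % (2**31))
    net = subject_multilayer(ts, window_len_s=window_len_s,
                             drop_initial=design.drop_initial)
    params = ModularityParams(n_repetitions=n_repetitions, seed=int(ss[1]) % (2**31))
    ensemble = repeat_optimization(net, params)
    wtp = int(round(window_len_s / design.tr_s))
    return planted_recovery_report(truth, ensemble, window_timepoints=wtp)


def _detection_design(seed: int, extra_switch: float) -> SimulationDesign:
    # scaled-down cohort for repeated power simulations: 40 regions in 4
    # blocks, 12 windows of 30 s, epochs of 60 s
    return SimulationDesign(
        n_regions=40, n_timepoints=122, rsn_sizes=(10, 10, 10, 10),
        group_sizes=(8, 8, 2, 2), seed=seed,
        group_effects={"CN_Abneg": GroupEffect(d_switch=extra_switch)},
    )


def flexibility_detection_experiment(
    seed: int,
    n_sims: int = 100,
    n_per_group: int = 8,
    base_switch: float = 0.2,
    n_louvain: int = 5,
    n_perm: int = 500,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulations detecting a doubled planted switch fraction.

    Each simulation draws ``n_per_group`` subjects at the baseline switch
    fraction and the same number with the fraction doubled, runs the full
    detection path, and tests the group difference in mean flexibility with
    a two-sided permutation test; success requires the doubled group higher
    and p < ``alpha``.
    """
    master = np.random.SeedSequence(seed)
    successes = 0
    for sim_seq in master.spawn(n_sims):
        states = sim_seq.generate_state(2 * n_per_group + 1)
        flex = {0.0: [], base_switch: []}
        for k in range(2 * n_per_group):
            extra = 0.0 if k < n_per_group else base_switch  # doubles the base
            design = _detection_design(seed=0, extra_switch=extra)
            ts, _ = generate_subject(design, int(states[k]) % (2**31))
            net = subject_multilayer(ts)
            params = ModularityParams(n_repetitions=n_louvain,
                                      seed=int(states[k]) % (2**31) + 1)
            ensemble = repeat_optimization(net, params)
            flex[extra].append(float(ensemble_node_flexibility(ensemble).mean()))
        doubled = np.array(flex[base_switch])
        base = np.array(flex[0.0])
        stat, p = permutation_test(doubled, base, n_perm=n_perm,
                                   seed=int(states[-1]) % (2**31))
        successes += (stat > 0) and (p < alpha)
    return successes / n_sims
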