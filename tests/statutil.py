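"""Small helpers for goodness-of-fit tests."""

import numpy as np
import scipy.stats


def chisquare_binned(observed, expected, min_expected=5.0):
    """Chi-square GOF after greedily merging consecutive cells so every
    bin's expectation is at least ``min_expected`` (heavy-tailed supports
    leave most raw cells far too sparse for the asymptotic test)."""
    obs_bins, exp_bins = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_bins.append(o_acc)
            exp_bins.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 and exp_bins:
        obs_bins[-1] += o_acc
        exp_bins[-1] += e_acc
    obs_bins = np.asarray(obs_bins)
    exp_bins = np.asarray(exp_bins) * obs_bins.sum() / np.sum(exp_bins)
    return scipy.stats.chisquare(obs_bins, f_exp=exp_bins)
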