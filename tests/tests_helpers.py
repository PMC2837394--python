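"""Shared fixture builders for the test suite."""

import numpy as np

from groupbms.bma import GaussianPosterior, SubjectPosteriorSet


def two_model_posterior_set(w: float = 0.7):
    """One subject, two models over two parameters.

    Parameter 0 is free in both models (means 2.0 and -1.0); parameter 1 is
    free only in model 1 (mean 0.5).  Returns the posterior set and the model
    weight vector (w, 1 - w).
    """

    def gp(means, free):
        free = np.asarray(free, dtype=bool)
        mu = np.where(free, np.asarray(means, dtype=float), 0.0)
        cov = np.zeros((2, 2))
        cov[np.flatnonzero(free), np.flatnonzero(free)] = 0.1**2
        return GaussianPosterior(mu, cov, free)

    posts = SubjectPosteriorSet(
        ((gp([2.0, 0.5], [True, True]), gp([-1.0, 0.0], [True, False])),),
        ("shared", "model1_only"),
    )
    return posts, np.array([w, 1.0 - w])
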