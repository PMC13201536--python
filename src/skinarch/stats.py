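"""Small statistical helpers shared across the pipeline."""

from __future__ import annotations


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-comparison significance threshold for a family-wise level.

    Parameters
    ----------
    alpha
        Family-wise significance level (e.g. 0.05).
    n_tests
        Number of comparisons in the family.

    Returns
    -------
    float
        ``alpha / n_tests``.
    """
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return alpha / n_tests
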