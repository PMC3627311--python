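"""Two-way fully within-subject (repeated-measures) ANOVA.

Implements the classical sums-of-squares decomposition for a balanced
subject x A x B layout with one observation per cell: each effect (A, B,
A x B) is tested against its own subject-interaction error term, i.e.
``F_A = MS_A / MS_{A x S}`` with ``df = (a-1), (a-1)(s-1)`` and analogously
for B and the interaction.  Used both for the Condition x Hemisphere analysis
of responding-channel betas and for the adult duration x token-variability
analysis of GLM z-scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rm_anova_2way", "anova_condition_hemisphere", "anova_2x2_within"]


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str,
    within: tuple[str, str],
    subject: str = "subject",
) -> pd.DataFrame:
    """Balanced two-way repeated-measures ANOVA from sums of squares.

    ``data`` is long-format with one row per subject x A-level x B-level.
    Returns a table with one row per effect (A, B, interaction) and columns
    ``ss, df1, df2, F, p``.  Raises if any cell is empty, duplicated, or the
    design has fewer than two subjects.
    """
    fa, fb = within
    req = {dv, fa, fb, subject}
    if not req.issubset(data.columns):
        raise ValueError(f"data must contain columns {sorted(req)}")
    subjects = sorted(data[subject].unique())
    a_levels = sorted(data[fa].unique())
    b_levels = sorted(data[fb].unique())
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    counts = data.groupby([subject, fa, fb], observed=True).size()
    expected = len(subjects) * len(a_levels) * len(b_levels)
    if len(counts) != expected or (counts != 1).any():
        raise ValueError("design must be balanced with one observation per cell")

    cube = (
        data.pivot_table(index=subject, columns=[fa, fb], values=dv, observed=True)
        .reindex(index=subjects, columns=pd.MultiIndex.from_product([a_levels, b_levels]))
        .to_numpy()
        .reshape(len(subjects), len(a_levels), len(b_levels))
    )
    ns, na, nb = cube.shape
    gm = cube.mean()
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_s = cube.mean(axis=(1, 2))
    m_ab = cube.mean(axis=0)
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)

    ss_a = ns * nb * ((m_a - gm) ** 2).sum()
    ss_b = ns * na * ((m_b - gm) ** 2).sum()
    ss_ab = ns * ((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2).sum()
    ss_as = nb * ((m_sa - m_a[None, :] - m_s[:, None] + gm) ** 2).sum()
    ss_bs = na * ((m_sb - m_b[None, :] - m_s[:, None] + gm) ** 2).sum()
    resid = (
        cube
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - gm
    )
    ss_abs = (resid**2).sum()

    rows = []
    for name, ss_eff, df1, ss_err, df2 in (
        (fa, ss_a, na - 1, ss_as, (na - 1) * (ns - 1)),
        (fb, ss_b, nb - 1, ss_bs, (nb - 1) * (ns - 1)),
        (f"{fa} x {fb}", ss_ab, (na - 1) * (nb - 1), ss_abs, (na - 1) * (nb - 1) * (ns - 1)),
    ):
        if ss_eff <= 0:
            f_val, p = 0.0, 1.0
        elif ss_err <= 0:
            f_val, p = np.inf, 0.0
        else:
            f_val = (ss_eff / df1) / (ss_err / df2)
            p = float(stats.f.sf(f_val, df1, df2))
        rows.append({"effect": name, "ss": ss_eff, "df1": df1, "df2": df2,
                     "F": f_val, "p": p})
    return pd.DataFrame(rows).set_index("effect")


def anova_condition_hemisphere(betas: pd.DataFrame) -> pd.DataFrame:
    """Condition x Hemisphere RM-ANOVA of responding-channel betas.

    ``betas``: long-format with columns ``subject, condition, hemisphere,
    beta`` (one value per subject and cell, e.g. the responding channel's
    beta and its hemispheric counterpart's).
    """
    return rm_anova_2way(betas, dv="beta", within=("condition", "hemisphere"))


def anova_2x2_within(z_scores: pd.DataFrame) -> pd.DataFrame:
    """Duration x token-variability RM-ANOVA of per-session GLM z-scores.

    ``z_scores``: long-format with columns ``subject, duration, tokens, z``
    where ``duration`` is the target-block length level (short/long) and
    ``tokens`` the token-variability level (single/multi).
    """
    return rm_anova_2way(z_scores, dv="z", within=("duration", "tokens"))
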