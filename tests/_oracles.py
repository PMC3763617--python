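"""Independent oracles used to cross-check the projection engine.

The Leslie-matrix construction below is written directly from the linear
algebra of one cohort-component step, without reference to the loop-based
engine: the state is the stacked vector [male; female] over the 17 age
groups, survivorship fills a sub-diagonal, the pooled open interval adds a
diagonal corner entry, and births contribute a first-row block over the
female entries (mid-period exposure makes the births linear in the start
population).
"""

import numpy as np

N = 17
REPRO = range(3, 10)  # 15-19 ... 45-49


def leslie_matrix(surv_m, surv_f, asfr_rates, srb=105.0, step=5.0) -> np.ndarray:
    """34x34 one-step projection matrix over [male(17); female(17)].

    ``surv_m``/``surv_f`` are (S_birth, S[15 closed ratios], S_open)
    triples; ``asfr_rates`` the 7 annual age-specific fertility rates.
    """
    sb_m, s_m, so_m = surv_m
    sb_f, s_f, so_f = surv_f
    A = np.zeros((2 * N, 2 * N))

    # survivorship blocks: male rows 0..16, female rows 17..33
    for off, s, so in ((0, s_m, so_m), (N, s_f, so_f)):
        for i in range(15):
            A[off + i + 1, off + i] = s[i]
        A[off + N - 1, off + N - 2] = so
        A[off + N - 1, off + N - 1] = so

    # births: B = step * sum_g f_g * (F_g + F'_g)/2 where F'_g = F_{g-1} * s_f[g-1]
    # (the survivorship-only pass), so B is linear in the female start vector.
    b_row = np.zeros(N)
    for gi, g in enumerate(REPRO):
        f = asfr_rates[gi]
        b_row[g] += step * f * 0.5
        b_row[g - 1] += step * f * 0.5 * s_f[g - 1]
    male_share = srb / (100.0 + srb)
    A[0, N : 2 * N] = b_row * male_share * sb_m
    A[N, N : 2 * N] = b_row * (1.0 - male_share) * sb_f
    return A
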