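import numpy as np
import pytest

import hemofluid as hf


@pytest.fixture(scope="session")
def reference_subjects():
    return hf.load_reference_parameters()


@pytest.fixture(scope="session")
def lr1(reference_subjects):
    p = reference_subjects[0]
    assert p.subject_id == "LR1"
    return p


@pytest.fixture(scope="session")
def lr2(reference_subjects):
    p = reference_subjects[1]
    assert p.subject_id == "LR2"
    return p


@pytest.fixture(scope="session")
def sheep_protocol_lr1(lr1):
    """The synthetic sheep protocol for a 40-kg subject, with the stand-in
    closed-loop infusion generated against LR1."""
    return hf.make_sheep_protocol(weight_kg=40.0, params=lr1)


@pytest.fixture(scope="session")
def lr2_synthetic():
    """Default-noise synthetic sheep-study data for subject LR2."""
    subjects = hf.load_reference_parameters()
    lr2 = subjects[1]
    protocol, result, series = hf.make_synthetic_subject_data(lr2, seed=7)
    return lr2, protocol, result, series


def euler_reference(thetas: np.ndarray, protocol, t_grid: np.ndarray,
                    dt: float = 0.001, sv_hr_sign: float = -1.0) -> np.ndarray:
    """Independent fixed-step Euler oracle (plain numpy, vectorized over
    subjects), written directly from the model equations.

    Returns outputs of shape (len(t_grid), n_subjects, 6) in the order
    BV, HCT, HR, SV, CO, BP.
    """
    th = {name: thetas[:, j].copy() for j, name in enumerate(hf.PARAM_NAMES)}
    n = thetas.shape[0]
    rU = np.zeros(n); rV = np.zeros(n)
    bv = th["BV0"].copy(); rbc = th["HCT0"] * th["BV0"]
    rhvl = np.zeros(n); hvt = np.zeros(n); hvl = np.zeros(n)
    eint = np.zeros(n); hut = np.zeros(n)
    sv = th["SV0"].copy(); tpr = th["TPR0"].copy()

    def record():
        H = th["H0"] + hvt + hvl - hut
        return np.stack([bv, rbc / bv, H, sv, H * sv, H * sv * tpr], axis=-1)

    edges = np.append(protocol.times, protocol.duration)
    out = np.empty((len(t_grid), n, 6))
    assert t_grid[0] == 0.0
    out[0] = record()
    out_k = 1
    for i in range(len(edges) - 1):
        a, b = edges[i], edges[i + 1]
        U, V = float(protocol.infusion[i]), float(protocol.loss[i])
        nsteps = int(round((b - a) / dt))
        for k in range(nsteps):
            d_rU = th["A_U_BV"] * rU + U / (1 + th["alpha_U"])
            d_rV = th["A_V_BV"] * rV - V / (1 + th["alpha_V"])
            q = th["K_P_BV"] * (bv - th["BV0"] - (rU + rV))
            d_bv = U - V - q
            d_rbc = -V * (rbc / bv)
            d_rhvl = th["G_V_L"] * V ** th["P_V_L"] if V > 0 else np.zeros(n)
            d_hvt = th["G_V_T"] * V
            e = rhvl - hvt - hvl
            d_hvl = th["K_P_H"] * e + th["K_I_H"] * eint
            d_hut = th["G_U_T"] * U ** th["P_U_T"] if U > 0 else np.zeros(n)
            dH = d_hvl + d_hvt - d_hut
            d_sv = (th["A_SV"] * (sv - th["SV0"]) + th["G_BV"] * d_bv
                    + th["K_P_SV"] * (th["r_SV"] - sv) + sv_hr_sign * th["G_HR"] * dH)
            H = th["H0"] + hvt + hvl - hut
            d_tpr = th["A_BP"] * (tpr - th["TPR0"]) + th["K_P_BP"] * (th["r_BP"] - H * sv * tpr)
            rU += dt * d_rU; rV += dt * d_rV; bv += dt * d_bv; rbc += dt * d_rbc
            rhvl += dt * d_rhvl; hvt += dt * d_hvt; hvl += dt * d_hvl
            eint += dt * e; hut += dt * d_hut; sv += dt * d_sv; tpr += dt * d_tpr
            t_now = a + (k + 1) * dt
            while out_k < len(t_grid) and t_grid[out_k] <= t_now + 1e-9:
                out[out_k] = record()
                out_k += 1
    assert out_k == len(t_grid)
    return out
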