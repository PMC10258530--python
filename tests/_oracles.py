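"""Independent brute-force reference implementations used as oracles."""

import numpy as np


def naive_sync_map(vi, vj, fs, max_lag_ms, step_ms, window_s):
    """Independent triple-loop reference: explicit lag shift, per-sample
    signed cosine, explicit window sum, final abs."""
    n_steps = int(round(max_lag_ms / step_ms))
    lags_ms = [k * step_ms for k in range(-n_steps, n_steps + 1)]
    w = int(round(window_s * fs))
    t_i = np.arange(vi.shape[0]) / fs
    max_lag_s = max_lag_ms / 1000.0
    lo, hi = max_lag_s, min(t_i[-1], (vj.shape[0] - 1) / fs - max_lag_s)
    t_valid = t_i[(t_i >= lo - 1e-12) & (t_i <= hi + 1e-12)]
    vi_valid = vi[(t_i >= lo - 1e-12) & (t_i <= hi + 1e-12)]
    t_src = np.arange(vj.shape[0]) / fs

    n_out = t_valid.size - w + 1
    C = np.zeros((n_out, len(lags_ms)))
    for li, lag in enumerate(lags_ms):
        cs = []
        for ti, t in enumerate(t_valid):
            tq = t + lag / 1000.0
            vjt = np.array([np.interp(tq, t_src, vj[:, ax]) for ax in range(3)])
            a, b = vi_valid[ti], vjt
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            cs.append(0.0 if na < 1e-9 or nb < 1e-9 else float(a @ b / (na * nb)))
        for w0 in range(n_out):
            C[w0, li] = abs(sum(cs[w0:w0 + w]) / w)
    return np.array(lags_ms), C


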