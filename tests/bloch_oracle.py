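"""Independent isochromat Bloch simulator used as an oracle for the EPG
engine.

Gradient spoiling is modeled by a uniform fan of intra-voxel dephasing
angles (one increment per configuration shift); RF pulses rotate every
isochromat about the y axis (matching the constant-phase convention of the
EPG engine), and the recorded signal is the complex mean transverse
magnetization decayed to the echo time.  The physics here is integrated
per isochromat — entirely independent of the configuration-state algebra
it checks.
"""

import numpy as np

_RELAX, _RF, _RECORD, _INVERT, _SATURATE, _SHIFT = 0, 1, 2, 3, 4, 5


def simulate_events_bloch(stream, t1, t2, b1, fa_train_deg, n_rep=1,
                          n_spins=2000):
    """Run an epg.EventStream with brute-force isochromat integration.

    Returns the final repetition's recorded signals (complex array).
    """
    fa = np.deg2rad(np.asarray(fa_train_deg, dtype=float))
    psi = 2.0 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    rot = np.exp(1j * psi)
    mxy = np.zeros(n_spins, dtype=complex)
    mz = np.ones(n_spins)
    durs = stream.durations
    e1 = np.exp(-durs / t1)
    e2 = np.exp(-durs / t2)
    out = np.zeros(stream.n_records, dtype=complex)
    for rep in range(n_rep):
        rec = 0
        for code, arg in zip(stream.codes, stream.args):
            if code == _RELAX:
                mxy = mxy * e2[arg]
                mz = 1.0 + (mz - 1.0) * e1[arg]
            elif code == _RF:
                a = fa[arg] * b1
                ca, sa = np.cos(a), np.sin(a)
                mx = mxy.real
                mx_new = ca * mx + sa * mz
                mz = -sa * mx + ca * mz
                mxy = mx_new + 1j * mxy.imag
            elif code == _RECORD:
                if rep == n_rep - 1:
                    out[rec] = np.mean(mxy) * e2[arg]
                rec += 1
            elif code == _INVERT:
                mz = -mz
                mxy = np.zeros_like(mxy)
            elif code == _SATURATE:
                mxy = np.zeros_like(mxy)
                mz = np.zeros_like(mz)
            else:  # gradient spoiling: advance the dephasing fan
                mxy = mxy * rot
    return out


def fisp_stream(n_tr, te_ms, tr_ms):
    """A plain FISP subsequence starting from equilibrium."""
    from vistamrf.epg import StreamBuilder

    b = StreamBuilder()
    for j in range(n_tr):
        b.rf(j).record(te_ms).relax(tr_ms).shift()
    return b.build()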