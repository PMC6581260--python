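"""Optional numba acceleration for the trial-loop likelihood kernels.

The kernels in :mod:`hbinfer.models` are written as plain scalar loops so
they run unchanged with or without numba; when numba is importable they are
JIT-compiled, which makes subject-level optimization roughly two orders of
magnitude faster.
"""

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def maybe_jit(func):
        return _njit(cache=False)(func)

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def maybe_jit(func):
        return func

    HAVE_NUMBA = False
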