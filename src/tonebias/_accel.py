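"""Optional numba acceleration.

All numerical kernels are written as plain scalar/loop Python so that they
compile under numba when it is available and still run (slowly) without it.
"""

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap
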