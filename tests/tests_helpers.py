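"""Shared toy-model constructors for the test suite."""

import numpy as np

from grnest.model import GRNModel


def decoupled_model(a=0.5, alpha0=0.9, beta0=0.9):
    """n=2 model with all couplings off: each channel is x(k+1) = -a x(k)."""
    I2 = np.eye(2)
    return GRNModel(
        A=a * I2, B=0 * I2, C=a * I2, D=0 * I2, E=0 * I2, F=0 * I2,
        H=1e-6 * I2, Lx=I2, Ly=I2, M=I2, N=I2,
        rho1=0, rho2=0, delta_m=0, delta_M=1, tau_m=0, tau_M=1,
        alpha0=alpha0, beta0=beta0,
    )
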