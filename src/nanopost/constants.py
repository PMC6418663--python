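"""Reduced Lennard-Jones unit system and model constants.

All quantities in the package are expressed in reduced units: the bead
diameter sigma is the unit of length, the WCA well depth epsilon the unit
of energy, the bead mass m_o the unit of mass, and tau = sigma*(m_o/eps)^1/2
the unit of time.  k_B*T = 1 at the reference temperature T = 1.
"""

import math

EPSILON: float = 1.0
SIGMA: float = 1.0
MASS: float = 1.0

#: WCA cutoff 2^(1/6) sigma (minimum of the Lennard-Jones potential).
R_CUT: float = 2.0 ** (1.0 / 6.0)
R_CUT2: float = 2.0 ** (1.0 / 3.0)

#: FENE spring constant (eps/sigma^2) and maximal bond extension (sigma).
FENE_KAPPA: float = 30.0
FENE_R0: float = 1.5

#: Equilibrium effective bond length of the combined FENE + WCA bond (sigma).
BOND_LENGTH: float = 0.97

#: Effective bead size of the touching-bead model (sigma); added to the bare
#: post diameter when mapping to the effective post diameter d_p = D_p + w.
BEAD_SIZE: float = 0.9

#: Odijk extension amplitude for a cylindrical channel.
ODIJK_A: float = 0.1701

SQRT2: float = math.sqrt(2.0)
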