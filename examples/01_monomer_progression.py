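"""Vibronic progression of a single displaced oscillator.

Builds the minimal FC|VG model (one bright state, one mode with
Huang-Rhys factor S = 0.5), prints its Franck-Condon stick progression,
the broadened absorption maximum, and the parameters recovered back from
the spectrum alone.
"""

import numpy as np

from lvcspec import (fcvg_spectrum, make_displaced_monomer,
                     recover_progression_parameters, stick_spectrum_fcvg)

H = make_displaced_monomer(vertical_energy=2.0, frequencies=(0.15,),
                           huang_rhys=(0.5,))
state, modes = H.states[0], H.modes

prog = stick_spectrum_fcvg(state, modes, max_quanta=5)
print("0-0 line at %.3f eV" % prog.e00)
for pos, inten in zip(prog.positions, prog.intensities):
    print("  stick %.3f eV  intensity %.4f" % (pos, inten))
print("I(0-1)/I(0-0) = %.3f  (equals S)" %
      (prog.intensities[1] / prog.intensities[0]))

omega = np.linspace(1.5, 3.0, 3001)
spec = fcvg_spectrum(H, t_max=200.0, hwhm=0.02, omega=omega)
print("broadened maximum at %.3f eV" % spec.max_position)

w_est, s_est = recover_progression_parameters(omega, spec.total)
print("recovered from the spectrum: w = %.4f eV, S = %.3f" % (w_est, s_est))
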