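# PLACEHOLDER dynamically-scaled roboflapper parameter set.
#
# provenance: placeholder -- NOT measured table values.  Inertia estimated
# from the published wing geometry (10 x 3.6 x 0.5 cm acrylic plate
# rotating about one end, plus flat-plate added mass in water); the torsion
# spring stiffness is back-computed from the published natural period
# Tn = 0.416 s via k_rot = I (2 pi / Tn)^2.  The robot transmission and
# actuator length are identity (T = 1 rad/m, L = 1 m): all scaling is
# absorbed into the feedback gain, as in the hardware controller.
name: roboflapper
provenance: placeholder
I_kgm2: 4.1e-4
k_Npm: 0.0935313   # rotational N m/rad stored with T = 1
T_radpm: 1.0
L_m: 1.0
Gamma_Nms2: 6.3e-4
c_lin_Nms: 0.0
fs_Hz: 2.4
dt_s: 1.0e-3
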