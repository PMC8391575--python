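compound,dE_vdw,dE_elec,dG_MM_reported,dG_polar_pb,dG_nonpolar_pb,dG_polar_gb,dG_nonpolar_gb,dG_bind_pb_reported,dG_bind_gb_reported
CA030,-25.81,-40.86,-66.67,41.45,-5.42,36.62,-5.42,-25.22,-30.06
BTB03075,-19.43,-39.35,-58.78,39.53,-5.94,31.97,-5.64,-19.25,-26.81
KM02922,-29.50,-51.66,-81.66,46.48,-6.61,38.96,-6.61,-34.68,-42.20
RF02795,-17.39,-58.86,-76.25,44.32,-6.38,37.24,-6.38,-31.93,-39.01
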