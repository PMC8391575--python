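compound,binding_energy,ki_um,intermolecular_energy,vdw_hb_desolv,electrostatic,internal_energy,torsional_free_energy
AW01196,-6.52,22.02,-6.37,-6.83,0.46,-0.62,2.47
BTB03075,-8.17,1.02,-8.45,-8.42,-0.03,-1.37,1.65
BTB11814,-7.07,6.52,-8.04,-7.94,-0.10,-1.50,2.47
HTS05162,-7.65,2.46,-7.88,-7.77,-0.11,-0.87,1.10
JFD02054,-6.08,35.21,-7.56,-7.60,0.04,-1.26,2.74
JP00474,-7.60,2.69,-8.08,-8.45,0.36,-1.71,2.20
KM02757,-7.31,4.41,-7.72,-7.43,-0.28,-2.61,3.02
KM02759,-8.16,1.04,-9.25,-9.19,-0.06,-1.93,3.02
KM02760,-7.31,4.41,-7.42,-7.37,-0.05,-2.91,3.02
KM02777,-7.53,3.01,-8.22,-8.25,0.03,-2.61,3.29
KM02922,-8.19,0.99,-8.47,-8.47,-0.03,-2.19,2.47
RF02795,-9.18,0.18,-9.44,-8.00,-1.44,-0.84,1.10
RJC00586,-6.29,24.43,-7.84,-7.81,-0.03,-1.20,2.74
S12294,-6.87,20.92,-6.45,-6.75,0.30,-0.79,1.37
SPB02418,-7.15,5.75,-7.91,-7.62,-0.29,-0.61,1.37
SPB03394,-6.76,11.11,-7.01,-7.08,0.08,-0.85,1.10
SPB03600,-8.01,1.35,-8.27,-8.15,-0.12,-0.83,1.10
SPB08054,-6.56,15.53,-8.21,-8.16,-0.05,-0.82,2.47
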