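# Seven residue-level physicochemical scales used by the auto-covariance
# encoder, one row per residue in PSI-BLAST column order.  Values follow
# published AAindex scales: hydrophobicity (Argos 1982), hydrophilicity
# (Hopp-Woods 1981), net charge (Klein 1984), van der Waals volume
# (Fauchere 1988), free energy of solution in water (Charton 1982),
# side-chain interaction parameter (Krigbaum-Komoriya 1979), accessible
# surface area (Chothia 1976).  Table version: 1.
residue,hydrophobicity,hydrophilicity,net_charge,van_der_waals,free_energy_solution,side_chain_interaction,accessible_surface_area
A,0.61,-0.5,0,1.00,-0.368,27.5,115
R,0.60,3.0,1,6.13,-1.03,105.0,225
N,0.06,0.2,0,2.95,0.0,58.7,160
D,0.46,3.0,-1,2.78,2.06,40.0,150
C,1.07,-1.0,0,2.43,4.53,44.6,135
Q,0.00,0.2,0,3.95,0.731,80.7,180
E,0.47,3.0,-1,3.78,1.77,62.0,190
G,0.07,0.0,0,0.00,-0.525,0.0,75
H,0.61,-0.5,0,4.66,0.0,79.0,195
I,2.22,-1.8,0,4.00,0.791,93.5,175
L,1.53,-1.8,0,4.00,1.07,93.5,170
K,1.15,3.0,1,4.77,0.0,100.0,200
M,1.18,-1.3,0,4.43,0.656,94.1,185
F,2.02,-2.5,0,5.89,1.06,115.5,210
P,1.95,0.0,0,2.72,-2.24,41.9,145
S,0.05,0.3,0,1.60,-0.524,29.3,115
T,0.05,-0.4,0,2.60,0.0,51.3,140
W,2.65,-3.4,0,8.08,1.60,145.5,255
Y,1.88,-2.3,0,6.47,4.91,117.3,230
V,1.32,-1.5,0,3.00,0.401,71.5,155
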