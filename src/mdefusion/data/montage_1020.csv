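name,x,y,z
Fp1,-0.29389263,0.90450850,0.30901699
Fp2,0.29389263,0.90450850,0.30901699
F3,-0.43302743,0.64541636,0.62922569
F4,0.43302743,0.64541636,0.62922569
C3,-0.58778525,0.00000000,0.80901699
C4,0.58778525,0.00000000,0.80901699
P3,-0.43302743,-0.64541636,0.62922569
P4,0.43302743,-0.64541636,0.62922569
O1,-0.29389263,-0.90450850,0.30901699
O2,0.29389263,-0.90450850,0.30901699
F7,-0.76942088,0.55901699,0.30901699
F8,0.76942088,0.55901699,0.30901699
T7,-0.95105652,0.00000000,0.30901699
T8,0.95105652,0.00000000,0.30901699
P7,-0.76942088,-0.55901699,0.30901699
P8,0.76942088,-0.55901699,0.30901699
FCz,0.00000000,0.30901699,0.95105652
CPz,0.00000000,-0.30901699,0.95105652
Oz,0.00000000,-0.95105652,0.30901699
Fz,0.00000000,0.58778525,0.80901699
Cz,0.00000000,0.00000000,1.00000000
Pz,0.00000000,-0.58778525,0.80901699
Fpz,0.00000000,0.95105652,0.30901699
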