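# Synthetic surname ethnicity table (fixture): name <TAB> label <TAB> share.
# Stand-in with made-up shares in the layout of a census surname export;
# a real conversion drops in unchanged.
yoder	white	0.985
yoder	black	0.005
yoder	asian	0.005
yoder	hispanic	0.005
olson	white	0.955
olson	black	0.015
olson	asian	0.010
olson	hispanic	0.020
washington	black	0.895
washington	white	0.055
washington	asian	0.010
washington	hispanic	0.040
jefferson	black	0.755
jefferson	white	0.185
jefferson	asian	0.010
jefferson	hispanic	0.050
nguyen	asian	0.965
nguyen	white	0.015
nguyen	black	0.005
nguyen	hispanic	0.015
tran	asian	0.955
tran	white	0.020
tran	black	0.005
tran	hispanic	0.020
garcia	hispanic	0.905
garcia	white	0.060
garcia	black	0.005
garcia	asian	0.030
rodriguez	hispanic	0.935
rodriguez	white	0.040
rodriguez	black	0.005
rodriguez	asian	0.020
smith	white	0.705
smith	black	0.230
smith	asian	0.015
smith	hispanic	0.050
lee	asian	0.420
lee	white	0.400
lee	black	0.170
lee	hispanic	0.010
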