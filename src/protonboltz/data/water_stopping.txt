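proton electronic stopping power, liquid water (I=75 eV)
E[MeV] S[MeV/cm]
2.500000e-02 3.497591e+03
2.797288e-02 3.233039e+03
3.129928e-02 2.988498e+03
3.502124e-02 2.762453e+03
3.918580e-02 2.553506e+03
4.384559e-02 2.360363e+03
4.905950e-02 2.181830e+03
5.489342e-02 2.016800e+03
6.142108e-02 1.864253e+03
6.872498e-02 1.723244e+03
7.689743e-02 1.592901e+03
8.604170e-02 1.472417e+03
9.627337e-02 1.361046e+03
1.077217e-01 1.258099e+03
1.205315e-01 1.162938e+03
1.348645e-01 1.074976e+03
1.509020e-01 9.936664e+02
1.688465e-01 9.185072e+02
1.889249e-01 8.490330e+02
2.113910e-01 7.848136e+02
2.365286e-01 7.254517e+02
2.646554e-01 6.705798e+02
2.961270e-01 6.198583e+02
3.313410e-01 5.729734e+02
3.707424e-01 5.296347e+02
4.148294e-01 4.895740e+02
4.641589e-01 4.525435e+02
5.193544e-01 4.183139e+02
5.811136e-01 3.866734e+02
6.502168e-01 3.574261e+02
7.275375e-01 3.303910e+02
8.140528e-01 3.054008e+02
9.108560e-01 2.823009e+02
1.019171e+00 2.609481e+02
1.140366e+00 2.412105e+02
1.275972e+00 2.229657e+02
1.427705e+00 2.061010e+02
1.597481e+00 1.905119e+02
1.787446e+00 1.761019e+02
2.000000e+00 1.627819e+02
2.039069e+00 1.604316e+02
2.078901e+00 1.581119e+02
2.119511e+00 1.558224e+02
2.160914e+00 1.535629e+02
2.203127e+00 1.513330e+02
2.246164e+00 1.491324e+02
2.290041e+00 1.469608e+02
2.334776e+00 1.448179e+02
2.380384e+00 1.427035e+02
2.426884e+00 1.406171e+02
2.474291e+00 1.385586e+02
2.522625e+00 1.365275e+02
2.571903e+00 1.345237e+02
2.622144e+00 1.325468e+02
2.673366e+00 1.305965e+02
2.725589e+00 1.286726e+02
2.778832e+00 1.267746e+02
2.833115e+00 1.249025e+02
2.888458e+00 1.230557e+02
2.944882e+00 1.212342e+02
3.002409e+00 1.194375e+02
3.061059e+00 1.176655e+02
3.120855e+00 1.159177e+02
3.181819e+00 1.141940e+02
3.243974e+00 1.124941e+02
3.307344e+00 1.108176e+02
3.371951e+00 1.091643e+02
3.437820e+00 1.075340e+02
3.504976e+00 1.059263e+02
3.573443e+00 1.043411e+02
3.643249e+00 1.027779e+02
3.714417e+00 1.012366e+02
3.786976e+00 9.971694e+01
3.860953e+00 9.821859e+01
3.936374e+00 9.674133e+01
4.013269e+00 9.528488e+01
4.091666e+00 9.384901e+01
4.171594e+00 9.243344e+01
4.253084e+00 9.103795e+01
4.336166e+00 8.966227e+01
4.420870e+00 8.830616e+01
4.507229e+00 8.696938e+01
4.595276e+00 8.565168e+01
4.685042e+00 8.435283e+01
4.776561e+00 8.307258e+01
4.869869e+00 8.181071e+01
4.964999e+00 8.056697e+01
5.061987e+00 7.934115e+01
5.160870e+00 7.813300e+01
5.261685e+00 7.694231e+01
5.364469e+00 7.576884e+01
5.469261e+00 7.461239e+01
5.576100e+00 7.347271e+01
5.685026e+00 7.234961e+01
5.796079e+00 7.124286e+01
5.909302e+00 7.015225e+01
6.024737e+00 6.907757e+01
6.142427e+00 6.801861e+01
6.262416e+00 6.697516e+01
6.384749e+00 6.594702e+01
6.509471e+00 6.493398e+01
6.636630e+00 6.393585e+01
6.766273e+00 6.295242e+01
6.898448e+00 6.198351e+01
7.033205e+00 6.102891e+01
7.170595e+00 6.008843e+01
7.310668e+00 5.916189e+01
7.453478e+00 5.824910e+01
7.599077e+00 5.734987e+01
7.747521e+00 5.646401e+01
7.898865e+00 5.559135e+01
8.053164e+00 5.473171e+01
8.210478e+00 5.388491e+01
8.370865e+00 5.305077e+01
8.534385e+00 5.222911e+01
8.701100e+00 5.141978e+01
8.871071e+00 5.062260e+01
9.044362e+00 4.983740e+01
9.221039e+00 4.906401e+01
9.401166e+00 4.830228e+01
9.584813e+00 4.755204e+01
9.772047e+00 4.681313e+01
9.962938e+00 4.608539e+01
1.015756e+01 4.536867e+01
1.035598e+01 4.466281e+01
1.055828e+01 4.396767e+01
1.076453e+01 4.328308e+01
1.097481e+01 4.260891e+01
1.118919e+01 4.194500e+01
1.140777e+01 4.129122e+01
1.163061e+01 4.064741e+01
1.185781e+01 4.001343e+01
1.208945e+01 3.938916e+01
1.232561e+01 3.877444e+01
1.256638e+01 3.816915e+01
1.281186e+01 3.757314e+01
1.306213e+01 3.698629e+01
1.331729e+01 3.640846e+01
1.357744e+01 3.583953e+01
1.384266e+01 3.527937e+01
1.411307e+01 3.472784e+01
1.438876e+01 3.418484e+01
1.466984e+01 3.365023e+01
1.495641e+01 3.312389e+01
1.524857e+01 3.260570e+01
1.554644e+01 3.209555e+01
1.585013e+01 3.159331e+01
1.615976e+01 3.109888e+01
1.647543e+01 3.061214e+01
1.679727e+01 3.013297e+01
1.712539e+01 2.966127e+01
1.745993e+01 2.919693e+01
1.780100e+01 2.873984e+01
1.814873e+01 2.828989e+01
1.850325e+01 2.784698e+01
1.886471e+01 2.741101e+01
1.923322e+01 2.698186e+01
1.960893e+01 2.655945e+01
1.999198e+01 2.614367e+01
2.038251e+01 2.573443e+01
2.078067e+01 2.533162e+01
2.118661e+01 2.493516e+01
2.160047e+01 2.454494e+01
2.202243e+01 2.416088e+01
2.245262e+01 2.378289e+01
2.289122e+01 2.341086e+01
2.333839e+01 2.304473e+01
2.379429e+01 2.268438e+01
2.425910e+01 2.232975e+01
2.473299e+01 2.198074e+01
2.521613e+01 2.163728e+01
2.570871e+01 2.129927e+01
2.621092e+01 2.096663e+01
2.672294e+01 2.063929e+01
2.724495e+01 2.031717e+01
2.777717e+01 2.000018e+01
2.831978e+01 1.968825e+01
2.887299e+01 1.938130e+01
2.943701e+01 1.907926e+01
3.001204e+01 1.878205e+01
3.059831e+01 1.848960e+01
3.119603e+01 1.820184e+01
3.180543e+01 1.791869e+01
3.242673e+01 1.764009e+01
3.306017e+01 1.736597e+01
3.370598e+01 1.709626e+01
3.436440e+01 1.683089e+01
3.503569e+01 1.656979e+01
3.572010e+01 1.631290e+01
3.641787e+01 1.606016e+01
3.712927e+01 1.581151e+01
3.785457e+01 1.556687e+01
3.859404e+01 1.532619e+01
3.934795e+01 1.508941e+01
4.011659e+01 1.485646e+01
4.090024e+01 1.462730e+01
4.169921e+01 1.440185e+01
4.251378e+01 1.418007e+01
4.334426e+01 1.396190e+01
4.419096e+01 1.374728e+01
4.505421e+01 1.353615e+01
4.593432e+01 1.332847e+01
4.683162e+01 1.312418e+01
4.774645e+01 1.292322e+01
4.867915e+01 1.272555e+01
4.963007e+01 1.253111e+01
5.059956e+01 1.233986e+01
5.158800e+01 1.215175e+01
5.259574e+01 1.196672e+01
5.362316e+01 1.178472e+01
5.467066e+01 1.160572e+01
5.573862e+01 1.142967e+01
5.682745e+01 1.125651e+01
5.793754e+01 1.108621e+01
5.906931e+01 1.091871e+01
6.022320e+01 1.075399e+01
6.139963e+01 1.059198e+01
6.259903e+01 1.043265e+01
6.382187e+01 1.027596e+01
6.506859e+01 1.012187e+01
6.633967e+01 9.970337e+00
6.763558e+01 9.821317e+00
6.895680e+01 9.674773e+00
7.030383e+01 9.530668e+00
7.167718e+01 9.388961e+00
7.307735e+01 9.249617e+00
7.450487e+01 9.112598e+00
7.596028e+01 8.977867e+00
7.744413e+01 8.845388e+00
7.895695e+01 8.715126e+00
8.049933e+01 8.587046e+00
8.207184e+01 8.461114e+00
8.367507e+01 8.337296e+00
8.530961e+01 8.215558e+00
8.697609e+01 8.095868e+00
8.867511e+01 7.978194e+00
9.040733e+01 7.862503e+00
9.217339e+01 7.748765e+00
9.397394e+01 7.636949e+00
9.580967e+01 7.527024e+00
9.768126e+01 7.418960e+00
9.958941e+01 7.312728e+00
1.015348e+02 7.208299e+00
1.035183e+02 7.105645e+00
1.055404e+02 7.004737e+00
1.076021e+02 6.905548e+00
1.097040e+02 6.808051e+00
1.118470e+02 6.712218e+00
1.140319e+02 6.618025e+00
1.162595e+02 6.525443e+00
1.185305e+02 6.434449e+00
1.208460e+02 6.345017e+00
1.232066e+02 6.257121e+00
1.256134e+02 6.170739e+00
1.280672e+02 6.085845e+00
1.305689e+02 6.002417e+00
1.331195e+02 5.920430e+00
1.357199e+02 5.839863e+00
1.383711e+02 5.760693e+00
1.410741e+02 5.682896e+00
1.438299e+02 5.606453e+00
1.466395e+02 5.531341e+00
1.495041e+02 5.457539e+00
1.524245e+02 5.385026e+00
1.554021e+02 5.313782e+00
1.584377e+02 5.243788e+00
1.615327e+02 5.175022e+00
1.646882e+02 5.107465e+00
1.679053e+02 5.041100e+00
1.711852e+02 4.975905e+00
1.745292e+02 4.911864e+00
1.779385e+02 4.848957e+00
1.814145e+02 4.787167e+00
1.849583e+02 4.726476e+00
1.885714e+02 4.666867e+00
1.922550e+02 4.608322e+00
1.960106e+02 4.550825e+00
1.998395e+02 4.494359e+00
2.037433e+02 4.438908e+00
2.077233e+02 4.384456e+00
2.117811e+02 4.330987e+00
2.159181e+02 4.278485e+00
2.201359e+02 4.226936e+00
2.244361e+02 4.176323e+00
2.288204e+02 4.126634e+00
2.332903e+02 4.077852e+00
2.378474e+02 4.029963e+00
2.424937e+02 3.982954e+00
2.472306e+02 3.936811e+00
2.520601e+02 3.891520e+00
2.569840e+02 3.847068e+00
2.620040e+02 3.803441e+00
2.671221e+02 3.760627e+00
2.723402e+02 3.718612e+00
2.776602e+02 3.677385e+00
2.830842e+02 3.636933e+00
2.886140e+02 3.597243e+00
2.942520e+02 3.558305e+00
3.000000e+02 3.520105e+00
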