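macroscopic nuclear cross sections, protons in liquid water
E[MeV] sig_el_H[1/cm] sig_el_A[1/cm] sig_in_A[1/cm]
1.000000e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.049098e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.100607e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.154645e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.211336e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.270810e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.333205e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.398663e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.467335e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.539378e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.614959e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.694250e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.777435e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.864704e+00 2.139179e-02 2.340027e-02 0.000000e+00
1.956258e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.052306e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.153071e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.258783e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.369685e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.486032e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.608092e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.736145e+00 2.139179e-02 2.340027e-02 0.000000e+00
2.870484e+00 2.139179e-02 2.340027e-02 0.000000e+00
3.011420e+00 2.139179e-02 2.340027e-02 0.000000e+00
3.159275e+00 2.139179e-02 2.340027e-02 0.000000e+00
3.314390e+00 2.139179e-02 2.340027e-02 0.000000e+00
3.477121e+00 2.139179e-02 2.340027e-02 0.000000e+00
3.647841e+00 2.139179e-02 2.340027e-02 0.000000e+00
3.826944e+00 2.139179e-02 2.340027e-02 0.000000e+00
4.014840e+00 2.139179e-02 2.340027e-02 0.000000e+00
4.211961e+00 2.139179e-02 2.340027e-02 0.000000e+00
4.418761e+00 2.139179e-02 2.340027e-02 0.000000e+00
4.635714e+00 2.139179e-02 2.340027e-02 0.000000e+00
4.863319e+00 2.139179e-02 2.340027e-02 0.000000e+00
5.000000e+00 2.139179e-02 2.340027e-02 0.000000e+00
5.102100e+00 2.139179e-02 2.340027e-02 0.000000e+00
5.352604e+00 2.139179e-02 2.340027e-02 0.000000e+00
5.615407e+00 2.139179e-02 2.340027e-02 0.000000e+00
5.891113e+00 2.139179e-02 2.340027e-02 0.000000e+00
6.180356e+00 2.139179e-02 2.340027e-02 0.000000e+00
6.483801e+00 2.139179e-02 2.340027e-02 0.000000e+00
6.802144e+00 2.139179e-02 2.340027e-02 0.000000e+00
7.000000e+00 2.139179e-02 2.340027e-02 0.000000e+00
7.136117e+00 2.139179e-02 2.340027e-02 3.815699e-05
7.486487e+00 2.139179e-02 2.340027e-02 4.321660e-04
7.854060e+00 2.139179e-02 2.340027e-02 1.173941e-03
8.239681e+00 2.139179e-02 2.340027e-02 2.164943e-03
8.644234e+00 2.139179e-02 2.340027e-02 3.306631e-03
9.068651e+00 2.139179e-02 2.340027e-02 4.500468e-03
9.513905e+00 2.139179e-02 2.340027e-02 5.647912e-03
9.981021e+00 2.139179e-02 2.340027e-02 6.650424e-03
1.000000e+01 2.139179e-02 2.340027e-02 6.685792e-03
1.047107e+01 2.117193e-02 2.335899e-02 7.518874e-03
1.098518e+01 2.054040e-02 2.323416e-02 8.370578e-03
1.152453e+01 1.959784e-02 2.303496e-02 9.244853e-03
1.200000e+01 1.863545e-02 2.281592e-02 1.002869e-02
1.209037e+01 1.844528e-02 2.277062e-02 1.018335e-02
1.268398e+01 1.718377e-02 2.245038e-02 1.130735e-02
1.330674e+01 1.591434e-02 2.208348e-02 1.254593e-02
1.396008e+01 1.473802e-02 2.167916e-02 1.373146e-02
1.464550e+01 1.375587e-02 2.124665e-02 1.469632e-02
1.500000e+01 1.336987e-02 2.102316e-02 1.504303e-02
1.536456e+01 1.303171e-02 2.079519e-02 1.532713e-02
1.611894e+01 1.240197e-02 2.033402e-02 1.584392e-02
1.691035e+01 1.182287e-02 1.987238e-02 1.629517e-02
1.774062e+01 1.128284e-02 1.941951e-02 1.668257e-02
1.861165e+01 1.077034e-02 1.898464e-02 1.700781e-02
1.952545e+01 1.027379e-02 1.857701e-02 1.727260e-02
2.000000e+01 1.002740e-02 1.838593e-02 1.738306e-02
2.048411e+01 9.782573e-03 1.819722e-02 1.748635e-02
2.148984e+01 9.296304e-03 1.780194e-02 1.768825e-02
2.254496e+01 8.818830e-03 1.739052e-02 1.786457e-02
2.365187e+01 8.353699e-03 1.697093e-02 1.799282e-02
2.481314e+01 7.904461e-03 1.655117e-02 1.805047e-02
2.500000e+01 7.835812e-03 1.648597e-02 1.805164e-02
2.603142e+01 7.474665e-03 1.613923e-02 1.802739e-02
2.730952e+01 7.067861e-03 1.574310e-02 1.794841e-02
2.865036e+01 6.687598e-03 1.537077e-02 1.783603e-02
3.000000e+01 6.350688e-03 1.504303e-02 1.771735e-02
3.005705e+01 6.337420e-03 1.503024e-02 1.771246e-02
3.153279e+01 6.015333e-03 1.472698e-02 1.755672e-02
3.308100e+01 5.715380e-03 1.445184e-02 1.735068e-02
3.470521e+01 5.434234e-03 1.419119e-02 1.711177e-02
3.640918e+01 5.168568e-03 1.393138e-02 1.685740e-02
3.819680e+01 4.915055e-03 1.365876e-02 1.660499e-02
4.000000e+01 4.679454e-03 1.337158e-02 1.638019e-02
4.007220e+01 4.670370e-03 1.335969e-02 1.637196e-02
4.203967e+01 4.433446e-03 1.302419e-02 1.615854e-02
4.410374e+01 4.206680e-03 1.266193e-02 1.595030e-02
4.626916e+01 3.992209e-03 1.228845e-02 1.574006e-02
4.854089e+01 3.792171e-03 1.191930e-02 1.552063e-02
5.000000e+01 3.676714e-03 1.170014e-02 1.537732e-02
5.092416e+01 3.608187e-03 1.156806e-02 1.528262e-02
5.342445e+01 3.436832e-03 1.122553e-02 1.500957e-02
5.604749e+01 3.277840e-03 1.088719e-02 1.472684e-02
5.879932e+01 3.132225e-03 1.055260e-02 1.446817e-02
6.000000e+01 3.075070e-03 1.041251e-02 1.437445e-02
6.168626e+01 2.998187e-03 1.022132e-02 1.425784e-02
6.471495e+01 2.865824e-03 9.892923e-03 1.407163e-02
6.789234e+01 2.738413e-03 9.566954e-03 1.390102e-02
7.000000e+01 2.661975e-03 9.360109e-03 1.379822e-02
7.122573e+01 2.620838e-03 9.242463e-03 1.374138e-02
7.472278e+01 2.517987e-03 8.914530e-03 1.358806e-02
7.839154e+01 2.434744e-03 8.584960e-03 1.343645e-02
8.000000e+01 2.406576e-03 8.445711e-03 1.337158e-02
8.224042e+01 2.374109e-03 8.257442e-03 1.328518e-02
8.627828e+01 2.327911e-03 7.935664e-03 1.314337e-02
9.051439e+01 2.289256e-03 7.623313e-03 1.300583e-02
9.495848e+01 2.251942e-03 7.324076e-03 1.286556e-02
9.962078e+01 2.209764e-03 7.041642e-03 1.271552e-02
1.000000e+02 2.206028e-03 7.020082e-03 1.270300e-02
1.045120e+02 2.159129e-03 6.773027e-03 1.254735e-02
1.096433e+02 2.104119e-03 6.511094e-03 1.236525e-02
1.150266e+02 2.049525e-03 6.256542e-03 1.218341e-02
1.200000e+02 2.005480e-03 6.038481e-03 1.203443e-02
1.206742e+02 2.000091e-03 6.010120e-03 1.201602e-02
1.265991e+02 1.956009e-03 5.772575e-03 1.186741e-02
1.328149e+02 1.914844e-03 5.544652e-03 1.172885e-02
1.393359e+02 1.875607e-03 5.327101e-03 1.159205e-02
1.400000e+02 1.871782e-03 5.306112e-03 1.157825e-02
1.461770e+02 1.837315e-03 5.120667e-03 1.144869e-02
1.500000e+02 1.817292e-03 5.014344e-03 1.136585e-02
1.533540e+02 1.800782e-03 4.924387e-03 1.129019e-02
1.600000e+02 1.771508e-03 4.751453e-03 1.113459e-02
1.608834e+02 1.768005e-03 4.729165e-03 1.111375e-02
1.687825e+02 1.740376e-03 4.539246e-03 1.093076e-02
1.770695e+02 1.714215e-03 4.361503e-03 1.075404e-02
1.800000e+02 1.704658e-03 4.304665e-03 1.069727e-02
1.857633e+02 1.683977e-03 4.202809e-03 1.058715e-02
1.948839e+02 1.651693e-03 4.070037e-03 1.042878e-02
2.000000e+02 1.637809e-03 4.011475e-03 1.036298e-02
2.044523e+02 1.628609e-03 3.967698e-03 1.031803e-02
2.144906e+02 1.612120e-03 3.882562e-03 1.023191e-02
2.200000e+02 1.604384e-03 3.842461e-03 1.019192e-02
2.250217e+02 1.597009e-03 3.809253e-03 1.015904e-02
2.360699e+02 1.580820e-03 3.745209e-03 1.009600e-02
2.476605e+02 1.571282e-03 3.687868e-03 1.003935e-02
2.500000e+02 1.570960e-03 3.677186e-03 1.002869e-02
2.598201e+02 1.570960e-03 3.635115e-03 9.986617e-03
2.725768e+02 1.570960e-03 3.587231e-03 9.938733e-03
2.859599e+02 1.570960e-03 3.545209e-03 9.896712e-03
3.000000e+02 1.570960e-03 3.510041e-03 9.861543e-03
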