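# standardized actinic flux preset (analytic surrogate; non-authoritative, replaceable)
# solar zenith angle = 90 deg, ozone column = 500 DU, ground elevation 0 km
# generated by scripts/make_flux_tables.py
# label: surrogate zenith=90, O3=500DU, 0 km a.s.l.
wavelength_nm,flux_photons_cm2_s_nm
280.000000,0.000000000000e+00
281.000000,0.000000000000e+00
282.000000,0.000000000000e+00
283.000000,0.000000000000e+00
284.000000,0.000000000000e+00
285.000000,0.000000000000e+00
286.000000,0.000000000000e+00
287.000000,0.000000000000e+00
288.000000,0.000000000000e+00
289.000000,7.923995198735e-279
290.000000,2.718929898346e-244
291.000000,3.807971753544e-213
292.000000,3.499669210336e-185
293.000000,3.451726235676e-160
294.000000,6.023319994032e-138
295.000000,3.065522290695e-118
296.000000,7.448071596076e-101
297.000000,1.395750940714e-85
298.000000,3.201773419909e-72
299.000000,1.396213517872e-60
300.000000,1.753693592348e-50
301.000000,9.359909635439e-42
302.000000,3.045389700289e-34
303.000000,8.421922266161e-28
304.000000,2.682421727894e-22
305.000000,1.296465527645e-17
306.000000,1.219248017149e-13
307.000000,2.787618284340e-10
308.000000,1.889122299999e-07
309.000000,4.521794054279e-05
310.000000,4.459977138697e-03
311.000000,2.074192752980e-01
312.000000,5.113631550149e+00
313.000000,7.395098539697e+01
314.000000,6.843729827730e+02
315.000000,4.366145095193e+03
316.000000,2.045750071738e+04
317.000000,7.427115072676e+04
318.000000,2.185680136520e+05
319.000000,5.414498852671e+05
320.000000,1.165226478002e+06
321.000000,2.236073586675e+06
322.000000,3.909752898747e+06
323.000000,6.340058031393e+06
324.000000,9.674067873450e+06
325.000000,1.405459139523e+07
326.000000,1.962775078568e+07
327.000000,2.655303888546e+07
328.000000,3.501377396850e+07
329.000000,4.522682995800e+07
330.000000,5.745132459397e+07
331.000000,7.199643502144e+07
332.000000,8.922871734173e+07
333.000000,1.095793363578e+08
334.000000,1.335515566775e+08
335.000000,1.617287665970e+08
336.000000,1.947832322262e+08
337.000000,2.334857221934e+08
338.000000,2.787161038419e+08
339.000000,3.314749868256e+08
340.000000,3.928964752298e+08
341.000000,4.642620810969e+08
342.000000,5.470158477428e+08
343.000000,6.427807286235e+08
344.000000,7.533762655670e+08
345.000000,8.808376082381e+08
346.000000,1.027435914396e+09
347.000000,1.195700167676e+09
348.000000,1.388440446243e+09
349.000000,1.608772671719e+09
350.000000,1.860144863353e+09
351.000000,2.146364917476e+09
352.000000,2.471629926964e+09
353.000000,2.840557049695e+09
354.000000,3.258215928907e+09
355.000000,3.730162661969e+09
356.000000,4.262475307326e+09
357.000000,4.861790912404e+09
358.000000,5.535344037985e+09
359.000000,6.291006747093e+09
360.000000,7.137330018741e+09
361.000000,8.083586539069e+09
362.000000,9.139814814477e+09
363.000000,1.031686454333e+10
364.000000,1.162644317480e+10
365.000000,1.308116357545e+10
366.000000,1.469459271624e+10
367.000000,1.648130128483e+10
368.000000,1.845691412064e+10
369.000000,2.063816136263e+10
370.000000,2.304293019277e+10
371.000000,2.569031705159e+10
372.000000,2.860068019579e+10
373.000000,3.179569246200e+10
374.000000,3.529839409546e+10
375.000000,3.913324549745e+10
376.000000,4.332617974092e+10
377.000000,4.790465470005e+10
378.000000,5.289770463620e+10
379.000000,5.833599108025e+10
380.000000,6.425185284915e+10
381.000000,7.067935503371e+10
382.000000,7.765433679330e+10
383.000000,8.521445779400e+10
384.000000,9.339924312667e+10
385.000000,1.022501265435e+11
386.000000,1.118104918528e+11
387.000000,1.221257123158e+11
388.000000,1.332431878905e+11
389.000000,1.452123801745e+11
390.000000,1.580848448993e+11
391.000000,1.719142618382e+11
392.000000,1.867564619926e+11
393.000000,2.026694519275e+11
394.000000,2.197134351365e+11
395.000000,2.379508303208e+11
396.000000,2.574462864762e+11
397.000000,2.782666946886e+11
398.000000,3.004811965488e+11
399.000000,3.241611891046e+11
400.000000,3.493803262771e+11
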