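# standardized actinic flux preset (analytic surrogate; non-authoritative, replaceable)
# solar zenith angle = 60 deg, ozone column = 350 DU, ground elevation 0 km
# generated by scripts/make_flux_tables.py
# label: surrogate zenith=60, O3=350DU, 0 km a.s.l.
wavelength_nm,flux_photons_cm2_s_nm
280.000000,1.145499401132e-15
281.000000,4.690838366472e-13
282.000000,1.357101340721e-10
283.000000,2.753445216606e-08
284.000000,3.906658514380e-06
285.000000,3.881074786697e-04
286.000000,2.713117017916e-02
287.000000,1.345574686625e+00
288.000000,4.786523463794e+01
289.000000,1.237518622464e+03
290.000000,2.360737880736e+04
291.000000,3.378043066351e+05
292.000000,3.689747513618e+06
293.000000,3.132627893157e+07
294.000000,2.105698731133e+08
295.000000,1.141437550022e+09
296.000000,5.081085476759e+09
297.000000,1.890519860969e+10
298.000000,5.980157820679e+10
299.000000,1.634517713908e+11
300.000000,3.919739990173e+11
301.000000,8.366310943269e+11
302.000000,1.610613877705e+12
303.000000,2.831032538441e+12
304.000000,4.594658944976e+12
305.000000,6.955482799029e+12
306.000000,9.911589919404e+12
307.000000,1.340488498756e+13
308.000000,1.733231669413e+13
309.000000,2.156393836567e+13
310.000000,2.596230707673e+13
311.000000,3.039890009908e+13
312.000000,3.476527647024e+13
313.000000,3.897863057400e+13
314.000000,4.298265190833e+13
315.000000,4.674514919574e+13
316.000000,5.025389993346e+13
317.000000,5.351189574220e+13
318.000000,5.653277213149e+13
319.000000,5.933686184380e+13
320.000000,6.194804683993e+13
321.000000,6.439141252385e+13
322.000000,6.669161356038e+13
323.000000,6.887182131694e+13
324.000000,7.095311784056e+13
325.000000,7.295421449799e+13
326.000000,7.489139430510e+13
327.000000,7.677859918403e+13
328.000000,7.862760360269e+13
329.000000,8.044823290787e+13
330.000000,8.224859791696e+13
331.000000,8.403532730264e+13
332.000000,8.581378653464e+13
333.000000,8.758827721158e+13
334.000000,8.936221405091e+13
335.000000,9.113827904347e+13
336.000000,9.291855366451e+13
337.000000,9.470463082679e+13
338.000000,9.649770865449e+13
339.000000,9.829866828740e+13
340.000000,1.001081378903e+14
341.000000,1.019265449094e+14
342.000000,1.037541584312e+14
343.000000,1.055911232921e+14
344.000000,1.074374873724e+14
345.000000,1.092932233091e+14
346.000000,1.111582456688e+14
347.000000,1.130324244586e+14
348.000000,1.149155956995e+14
349.000000,1.168075696618e+14
350.000000,1.187081372479e+14
351.000000,1.206170749205e+14
352.000000,1.225341484897e+14
353.000000,1.244591160159e+14
354.000000,1.263917300261e+14
355.000000,1.283317392043e+14
356.000000,1.302788896773e+14
357.000000,1.322329259942e+14
358.000000,1.341935918721e+14
359.000000,1.361606307669e+14
360.000000,1.381337863107e+14
361.000000,1.401128026516e+14
362.000000,1.420974247183e+14
363.000000,1.440873984304e+14
364.000000,1.460824708667e+14
365.000000,1.480823904040e+14
366.000000,1.500869068318e+14
367.000000,1.520957714508e+14
368.000000,1.541087371572e+14
369.000000,1.561255585187e+14
370.000000,1.581459918406e+14
371.000000,1.601697952277e+14
372.000000,1.621967286398e+14
373.000000,1.642265539440e+14
374.000000,1.662590349625e+14
375.000000,1.682939375184e+14
376.000000,1.703310294778e+14
377.000000,1.723700807896e+14
378.000000,1.744108635235e+14
379.000000,1.764531519050e+14
380.000000,1.784967223488e+14
381.000000,1.805413534899e+14
382.000000,1.825868262132e+14
383.000000,1.846329236804e+14
384.000000,1.866794313562e+14
385.000000,1.887261370319e+14
386.000000,1.907728308473e+14
387.000000,1.928193053118e+14
388.000000,1.948653553226e+14
389.000000,1.969107781826e+14
390.000000,1.989553736158e+14
391.000000,2.009989437817e+14
392.000000,2.030412932883e+14
393.000000,2.050822292034e+14
394.000000,2.071215610647e+14
395.000000,2.091591008887e+14
396.000000,2.111946631782e+14
397.000000,2.132280649283e+14
398.000000,2.152591256319e+14
399.000000,2.172876672831e+14
400.000000,2.193135143804e+14
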