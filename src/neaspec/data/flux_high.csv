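# standardized actinic flux preset (analytic surrogate; non-authoritative, replaceable)
# solar zenith angle = 0 deg, ozone column = 200 DU, ground elevation 0 km
# generated by scripts/make_flux_tables.py
# label: surrogate zenith=0, O3=200DU, 0 km a.s.l.
wavelength_nm,flux_photons_cm2_s_nm
280.000000,3.439568325534e+05
281.000000,1.959796163411e+06
282.000000,1.010658451396e+07
283.000000,4.707259272594e+07
284.000000,1.978558576012e+08
285.000000,7.507692049898e+08
286.000000,2.575482491493e+09
287.000000,8.006161663524e+09
288.000000,2.262380776863e+10
289.000000,5.833508509391e+10
290.000000,1.378455873624e+11
291.000000,2.999204517120e+11
292.000000,6.038729213249e+11
293.000000,1.131008393820e+12
294.000000,1.980879507132e+12
295.000000,3.261467119621e+12
296.000000,5.074449607711e+12
297.000000,7.498675624071e+12
298.000000,1.057588457122e+13
299.000000,1.430219394175e+13
300.000000,1.862717186029e+13
301.000000,2.346020139164e+13
302.000000,2.868212564708e+13
303.000000,3.415932051231e+13
304.000000,3.975741966696e+13
305.000000,4.535263812424e+13
306.000000,5.083961642844e+13
307.000000,5.613560916816e+13
308.000000,6.118148220491e+13
309.000000,6.594031707675e+13
310.000000,7.039449634345e+13
311.000000,7.454204788256e+13
312.000000,7.839284662269e+13
313.000000,8.196507510359e+13
314.000000,8.528216959947e+13
315.000000,8.837034406225e+13
316.000000,9.125669241587e+13
317.000000,9.396781505583e+13
318.000000,9.652888888671e+13
319.000000,9.896309289842e+13
320.000000,1.012913056241e+14
321.000000,1.035320012462e+14
322.000000,1.057012838473e+14
323.000000,1.078130120383e+14
324.000000,1.098789776835e+14
325.000000,1.119091121673e+14
326.000000,1.139117014843e+14
327.000000,1.158935975381e+14
328.000000,1.178604176296e+14
329.000000,1.198167274796e+14
330.000000,1.217662055241e+14
331.000000,1.237117878632e+14
332.000000,1.256557943291e+14
333.000000,1.276000368156e+14
334.000000,1.295459113919e+14
335.000000,1.314944758997e+14
336.000000,1.334465147750e+14
337.000000,1.354025927775e+14
338.000000,1.373630992077e+14
339.000000,1.393282840492e+14
340.000000,1.412982873207e+14
341.000000,1.432731627675e+14
342.000000,1.452528968709e+14
343.000000,1.472374240141e+14
344.000000,1.492266385143e+14
345.000000,1.512204041184e+14
346.000000,1.532185614570e+14
347.000000,1.552209338674e+14
348.000000,1.572273319199e+14
349.000000,1.592375569194e+14
350.000000,1.612514036038e+14
351.000000,1.632686622133e+14
352.000000,1.652891200718e+14
353.000000,1.673125627922e+14
354.000000,1.693387751906e+14
355.000000,1.713675419798e+14
356.000000,1.733986482940e+14
357.000000,1.754318800854e+14
358.000000,1.774670244242e+14
359.000000,1.795038697267e+14
360.000000,1.815422059288e+14
361.000000,1.835818246185e+14
362.000000,1.856225191386e+14
363.000000,1.876640846671e+14
364.000000,1.897063182801e+14
365.000000,1.917490190026e+14
366.000000,1.937919878499e+14
367.000000,1.958350278614e+14
368.000000,1.978779441293e+14
369.000000,1.999205438231e+14
370.000000,2.019626362108e+14
371.000000,2.040040326768e+14
372.000000,2.060445467381e+14
373.000000,2.080839940589e+14
374.000000,2.101221924626e+14
375.000000,2.121589619430e+14
376.000000,2.141941246743e+14
377.000000,2.162275050194e+14
378.000000,2.182589295372e+14
379.000000,2.202882269893e+14
380.000000,2.223152283447e+14
381.000000,2.243397667847e+14
382.000000,2.263616777058e+14
383.000000,2.283807987222e+14
384.000000,2.303969696679e+14
385.000000,2.324100325966e+14
386.000000,2.344198317824e+14
387.000000,2.364262137184e+14
388.000000,2.384290271153e+14
389.000000,2.404281228989e+14
390.000000,2.424233542072e+14
391.000000,2.444145763866e+14
392.000000,2.464016469870e+14
393.000000,2.483844257574e+14
394.000000,2.503627746397e+14
395.000000,2.523365577626e+14
396.000000,2.543056414346e+14
397.000000,2.562698941365e+14
398.000000,2.582291865136e+14
399.000000,2.601833913668e+14
400.000000,2.621323836443e+14
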