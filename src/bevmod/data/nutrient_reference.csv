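food_code,wweia_code,description,energy,carbohydrate,fiber,total_sugars,added_sugars,protein,total_fat,mufa,pufa,sfa,calcium,magnesium,potassium,sodium,vitamin_a,folate,vitamin_b12,vitamin_d
11100000,1004,"Milk, nfs (synthetic composite fixture)",54.222222,5.333333,0,5.555556,0,3.6,2.155556,0.564444,0.102222,1.288889,128.888889,12,159.111111,46,54.666667,5.111111,0.506667,1.328889
11511100,1202,"Milk, flavored, chocolate (synthetic fixture)",72,10.5,0.5,10.0,1.19,3.2,2.0,0.55,0.10,1.20,110,11,150,60,50,5,0.45,1.10
11320000,1404,"Soy beverage (synthetic fixture)",45,4.0,0.4,3.5,0.70,2.8,1.8,0.40,0.90,0.25,120,15,120,40,50,8,0.90,1.00
64100100,7002,"Apple juice, 100% (synthetic fixture)",46,11.3,0.2,9.6,0,0.1,0.1,0.0,0.03,0.02,8,5,101,4,0,0,0,0
92410310,7202,"Soft drink, cola (synthetic fixture)",41,10.6,0,10.6,2.50,0,0,0,0,0,2,1,2,4,0,0,0,0
92510610,7204,"Fruit drink (synthetic fixture)",45,11.5,0,11.2,2.60,0,0,0,0,0,4,2,15,10,1,1,0,0
95310560,7208,"Sports drink (synthetic fixture)",26,6.8,0,6.0,1.40,0,0,0,0,0,1,1,12,41,0,0,0,0
92101000,7302,"Coffee, with milk and sugar (synthetic fixture)",30,5.0,0,4.5,1.00,0.8,0.8,0.20,0.05,0.50,30,6,50,15,8,2,0.10,0.20
92400000,7804,"Soft drink, diet (synthetic fixture)",0,0,0,0,0,0,0,0,0,0,2,1,2,10,0,0,0,0
94000100,7702,"Water, bottled (synthetic fixture)",0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
57123000,5604,"Breakfast cereal, fortified (synthetic fixture)",380,84,7.0,30,6.50,7,3.0,1.00,0.80,0.70,330,60,170,500,500,680,5.00,3.30
58106210,5802,"Pizza, cheese (synthetic fixture)",266,33,2.3,3.6,0.50,11,9.7,2.80,1.70,4.50,188,20,172,598,74,90,0.50,0.10
27443000,2204,"Chicken and rice mixed dish (synthetic fixture)",180,15,0.9,1.2,0,11,7.5,2.90,1.60,1.90,20,18,180,320,15,25,0.20,0.10
63107010,6402,"Banana, raw (synthetic fixture)",89,22.8,2.6,12.2,0,1.1,0.33,0.03,0.07,0.11,5,27,358,1,3,20,0,0
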