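food_id,name,calories_kcal,carbs_g,protein_g,fat_g,fiber_g,glycemic_index,tags
F001,white rice (1 cup cooked),205,45,4.2,0.4,0.6,73,vegetarian
F002,brown rice (1 cup cooked),218,46,4.5,1.6,3.5,68,vegetarian
F003,quinoa (1 cup cooked),222,39,8.1,3.6,5.2,53,vegetarian
F004,chapati (2 medium),240,46,7.6,4.4,4.9,62,vegetarian;contains_gluten
F005,white bread (2 slices),160,30,5.4,2.0,1.6,75,vegetarian;contains_gluten
F006,multigrain bread (2 slices),180,30,7.0,3.0,4.0,53,vegetarian;contains_gluten
F007,idli (3 pieces),174,36,6.0,0.6,1.8,68,vegetarian
F008,dosa (1 large),168,29,3.9,3.7,1.4,66,vegetarian
F009,poha (1 plate),250,48,5.0,4.5,2.2,70,vegetarian
F010,upma (1 plate),230,38,6.5,6.0,3.0,64,vegetarian;contains_gluten
F011,oats porridge (1 bowl),166,28,5.9,3.6,4.0,55,vegetarian
F012,potato (1 medium boiled),130,29,2.9,0.1,2.7,78,vegetarian
F013,sweet potato (1 medium),112,26,2.0,0.1,3.9,61,vegetarian
F014,pasta (1 cup cooked),221,43,8.1,1.3,2.5,49,vegetarian;contains_gluten
F015,noodles instant (1 pack),380,52,8.0,15.0,2.4,70,vegetarian;contains_gluten
F016,dal lentils (1 cup cooked),230,40,17.9,0.8,15.6,29,vegetarian
F017,chickpea curry (1 cup),269,45,14.5,4.2,12.5,28,vegetarian
F018,rajma kidney beans (1 cup),225,40,15.3,0.9,13.1,24,vegetarian
F019,paneer curry (1 cup),320,12,18.0,24.0,2.0,27,vegetarian;contains_dairy
F020,grilled chicken (150 g),247,0,46.5,5.4,0.0,0,none
F021,fish curry (1 cup),220,6,28.0,9.0,1.0,5,none
F022,egg omelette (2 eggs),188,1.2,12.6,14.2,0.0,0,vegetarian_egg
F023,tofu stir fry (1 cup),180,8,15.0,11.0,2.5,15,vegetarian
F024,greek yogurt plain (1 cup),150,9,20.0,4.0,0.0,11,vegetarian;contains_dairy
F025,mixed salad (1 bowl),60,10,2.5,1.5,4.5,15,vegetarian
F026,sauteed vegetables (1 cup),90,12,3.0,3.5,4.8,20,vegetarian
F027,fruit banana (1 medium),105,27,1.3,0.4,3.1,51,vegetarian
F028,fruit apple (1 medium),95,25,0.5,0.3,4.4,36,vegetarian
F029,fruit mango (1 cup),99,25,1.4,0.6,2.6,51,vegetarian
F030,fruit papaya (1 cup),55,14,0.9,0.4,2.5,60,vegetarian
F031,almonds (30 g),174,6.1,6.4,15.0,3.8,0,vegetarian;contains_nut
F032,peanut chikki (1 bar),160,18,5.0,8.0,1.5,65,vegetarian;contains_nut
F033,samosa (1 piece),262,24,4.7,17.0,2.1,72,vegetarian;contains_gluten
F034,gulab jamun (2 pieces),300,48,4.0,11.0,0.5,80,vegetarian;contains_dairy
F035,sweetened lassi (1 glass),220,35,6.0,6.0,0.0,66,vegetarian;contains_dairy
F036,fruit juice orange (1 glass),112,26,1.7,0.5,0.5,50,vegetarian
F037,sugary soda (1 can),140,39,0.0,0.0,0.0,63,vegetarian
F038,biscuits glucose (4 pieces),160,26,2.4,5.0,0.6,72,vegetarian;contains_gluten
F039,khichdi (1 plate),240,42,9.0,5.0,5.5,55,vegetarian
F040,vegetable biryani (1 plate),310,52,7.5,9.0,4.2,63,vegetarian
F041,curd rice (1 plate),260,44,7.0,6.0,1.2,64,vegetarian;contains_dairy
F042,millet roti (2 pieces),200,40,5.8,2.8,6.2,50,vegetarian
F043,sprouts salad (1 bowl),120,18,8.5,1.2,6.8,25,vegetarian
F044,boiled corn (1 cup),143,31,5.0,2.2,3.6,52,vegetarian
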